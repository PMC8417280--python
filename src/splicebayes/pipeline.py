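"""End-to-end assembly pipeline: k-mer table -> splicing graphs ->
candidate paths -> Bayesian transcript calls.

The pipeline is deterministic given a seed: graphs are processed in
lexicographic order of their smallest k-mer, a single seeded generator is
threaded through all Gibbs runs in that order, and reports are written
with sorted keys and no timestamps.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .candidates import enumerate_candidates
from .graph import ReadIndex, SplicingGraph, build_all_graphs
from .io import (
    AssembledTranscript,
    ReadPair,
    read_fastq,
    reverse_complement,
    write_transcripts_fasta,
)
from .kmers import build_kmer_table, filter_errors, iter_kmers
from .model import (
    FragmentLengthDist,
    GibbsConfig,
    _CandidateIndex,
    call_transcripts,
    estimate_flen_dist,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the assembler, with desk-scale defaults."""

    k: int = 25
    stranded: bool = True
    seed: int = 17
    max_candidates: int = 100
    min_transcript_length: int = 200
    min_dominance_ratio: float = 20.0
    min_kmer_count: int = 1
    min_seed_entropy: float = 1.5
    max_branches: int = 20
    anchor_window: int = 300
    min_pe_overlap: int = 15
    sweeps: int = 2000
    burn_in: int = 500
    pi: float = 0.5
    alpha: float = 1.0
    call_threshold: float = 0.5
    flen_mean: float = 250.0
    flen_sd: float = 25.0
    # input/output paths for run_pipeline (in-memory API ignores them)
    left: str | None = None
    right: str | None = None
    interleaved: str | None = None
    output_dir: str = "splicebayes_out"


def load_config_file(path: str | Path) -> dict:
    """Flat key=value config file; '#' comments and blank lines ignored."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


@dataclass
class AssemblyResult:
    transcripts: list[AssembledTranscript]
    graphs: list[SplicingGraph]
    report: dict
    posteriors: dict[str, list[tuple[str, float, float]]] = field(
        default_factory=dict
    )


def _assign_fragments(
    pairs: Sequence[ReadPair],
    graphs: Sequence[SplicingGraph],
    k: int,
    stranded: bool,
) -> dict[str, list[ReadPair]]:
    """Assign each fragment to the graph owning most of its k-mers."""
    owner: dict[str, int] = {}
    for gi, graph in enumerate(graphs):
        for km in graph.kmer_to_node:
            owner[km] = gi
    assignment: dict[str, list[ReadPair]] = {g.graph_id: [] for g in graphs}
    for pair in pairs:
        votes: dict[int, int] = {}
        mates = [pair.mate1]
        if pair.mate2:
            mates.append(reverse_complement(pair.mate2))
        for seq in mates:
            for km in iter_kmers(seq, k):
                gi = owner.get(km)
                if gi is None and not stranded:
                    gi = owner.get(reverse_complement(km))
                if gi is not None:
                    votes[gi] = votes.get(gi, 0) + 1
        if votes:
            best = max(votes.values())
            gi = min(g for g, v in votes.items() if v == best)
            assignment[graphs[gi].graph_id].append(pair)
    return assignment


def _estimate_flen(
    graphs: Sequence[SplicingGraph],
    assignment: dict[str, list[ReadPair]],
    config: PipelineConfig,
    max_obs: int = 5000,
) -> FragmentLengthDist:
    """Implied fragment lengths from unique placements on single-node graphs."""
    lengths: list[int] = []
    for graph in graphs:
        if len(graph.nodes) != 1:
            continue
        seq = next(iter(graph.nodes.values())).sequence
        idx = _CandidateIndex(seq, config.k)
        for pair in assignment.get(graph.graph_id, ()):
            if not pair.mate2:
                continue
            s1 = idx.mate_starts(pair.mate1)
            s2 = idx.mate_starts(reverse_complement(pair.mate2))
            if s1 and s2 and len(s1) == 1 and len(s2) == 1:
                flen = next(iter(s2)) + len(pair.mate2) - next(iter(s1))
                if flen > 0:
                    lengths.append(flen)
            if len(lengths) >= max_obs:
                break
        if len(lengths) >= max_obs:
            break
    return estimate_flen_dist(
        lengths, config.k, fallback=(config.flen_mean, config.flen_sd)
    )


def assemble_reads(
    pairs: Iterable[ReadPair], config: PipelineConfig
) -> AssemblyResult:
    """Run the full assembly on an in-memory read stream."""
    pairs = list(pairs)
    t0 = time.monotonic()
    table = build_kmer_table(pairs, config.k, config.stranded) if pairs else None
    if table is None or not table.counts:
        report = {
            "n_fragments": len(pairs),
            "n_kmers_raw": 0,
            "n_kmers_filtered": 0,
            "n_graphs": 0,
            "n_transcripts": 0,
            "graphs": [],
        }
        return AssemblyResult(transcripts=[], graphs=[], report=report)
    n_raw = len(table)
    table = filter_errors(
        table, config.min_dominance_ratio, config.min_kmer_count
    )
    logger.info("k-mer table: %d raw, %d after filtering", n_raw, len(table))
    index = ReadIndex(pairs, config.k, config.stranded)
    graphs = build_all_graphs(
        table,
        index,
        min_entropy=config.min_seed_entropy,
        max_branches=config.max_branches,
        anchor_window=config.anchor_window,
        min_pe_overlap=config.min_pe_overlap,
    )
    logger.info("constructed %d splicing graphs", len(graphs))
    assignment = _assign_fragments(pairs, graphs, config.k, config.stranded)
    flen_dist = _estimate_flen(graphs, assignment, config)
    gibbs = GibbsConfig(
        sweeps=config.sweeps,
        burn_in=config.burn_in,
        pi=config.pi,
        alpha=config.alpha,
        call_threshold=config.call_threshold,
    )
    rng = np.random.default_rng(config.seed)
    transcripts: list[AssembledTranscript] = []
    graph_reports = []
    posteriors: dict[str, list[tuple[str, float, float]]] = {}
    for graph in graphs:
        frags = assignment.get(graph.graph_id, [])
        try:
            candidates = enumerate_candidates(
                graph, config.max_candidates, flen_dist.mean
            )
            called, summary = call_transcripts(
                graph,
                candidates,
                frags,
                gibbs,
                rng,
                flen_dist=flen_dist,
                stranded=config.stranded,
                min_length=config.min_transcript_length,
            )
        except Exception as exc:
            raise RuntimeError(
                f"transcript calling failed in graph {graph.graph_id}: {exc}"
            ) from exc
        transcripts.extend(called)
        posteriors[graph.graph_id] = [
            (
                f"{graph.graph_id}.c{t + 1}",
                float(summary.expression_prob[t]),
                float(summary.mean_abundance[t]),
            )
            for t in range(len(candidates))
        ]
        graph_reports.append(
            {
                "graph_id": graph.graph_id,
                "n_nodes": len(graph.nodes),
                "n_edges": len(graph.edges),
                "n_candidates": len(candidates),
                "n_fragments": len(frags),
                "n_called": len(called),
            }
        )
    elapsed = time.monotonic() - t0
    logger.info("assembly finished in %.1f s", elapsed)
    report = {
        "n_fragments": len(pairs),
        "n_kmers_raw": n_raw,
        "n_kmers_filtered": len(table),
        "n_graphs": len(graphs),
        "n_transcripts": len(transcripts),
        "flen_mean": round(flen_dist.mean, 3),
        "flen_sd": round(flen_dist.sd, 3),
        "graphs": graph_reports,
    }
    return AssemblyResult(
        transcripts=transcripts,
        graphs=graphs,
        report=report,
        posteriors=posteriors,
    )


def run_pipeline(config: PipelineConfig) -> AssemblyResult:
    """File-based entry point: read FASTQ, assemble, write outputs.

    Writes ``transcripts.fasta``, ``report.json`` and one posterior TSV per
    graph under ``<output_dir>/posteriors/``.
    """
    if config.interleaved:
        reads = read_fastq(
            config.interleaved, interleaved=True, stranded=config.stranded
        )
    elif config.left and config.right:
        reads = read_fastq(config.left, config.right, stranded=config.stranded)
    elif config.left or config.right:
        raise ValueError("both --left and --right are required for paired files")
    else:
        reads = iter(())
    result = assemble_reads(reads, config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_transcripts_fasta(result.transcripts, outdir / "transcripts.fasta")
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    post_dir = outdir / "posteriors"
    post_dir.mkdir(exist_ok=True)
    for graph_id, rows in result.posteriors.items():
        with open(post_dir / f"{graph_id}.tsv", "w") as fh:
            fh.write("candidate_id\tposterior_prob\tmean_abundance\n")
            for cid, prob, ab in rows:
                fh.write(f"{cid}\t{prob:.6f}\t{ab:.6f}\n")
    return result
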