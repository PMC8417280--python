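"""Synthetic multi-isoform transcriptomes and paired-end read simulation.

The generator emulates the structure of an RNA-seq benchmark without any
external data: genes carry several isoforms built from shared exons by
exon skipping, alternative 5'/3' boundaries (exon truncation) and intron
retention (a merged exon variant); expression is drawn log-uniformly over
a wide FPKM range, with a configurable fraction of isoforms unexpressed.
Reads are 100-bp paired-end (optionally strand-specific) with Gaussian
fragment lengths and iid substitution errors.

Exon sequences are uniform-random DNA, so k-mer entropy is near the 2-bit
maximum and sequences are effectively unique — which is what makes exact
k-mer matching a lossless stand-in for alignment in the evaluation module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ReadPair, reverse_complement, write_fasta_sequences

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass
class SimulatedGene:
    """Ground-truth gene: exon parts, isoforms as exon-index lists, FPKMs."""

    gene_id: str
    exons: list[str]
    isoforms: list[list[int]]
    fpkm: list[float]

    def isoform_sequence(self, i: int) -> str:
        return "".join(self.exons[j] for j in self.isoforms[i])

    def isoform_id(self, i: int) -> str:
        return f"{self.gene_id}.i{i + 1}"


def _apply_event(
    parts: list[tuple],
    part_seqs: dict[tuple, str],
    exon_len_range: tuple[int, int],
    min_exon: int,
    rng: np.random.Generator,
) -> list[tuple] | None:
    """One alternative-splicing event on a parent isoform (list of part keys).

    Part keys sort genomically: base exon i -> (i, 1); truncated variant of
    exon i -> (i, 2, w); retained intron merging exons i, i+1 -> (i, 3).
    Returns the new part list, or None if the event is inapplicable.
    """
    event = rng.integers(0, 3)
    base_positions = [p for p in parts if p[1] == 1]
    if event == 0:  # exon skip (internal exon)
        internal = parts[1:-1]
        if not internal:
            return None
        drop = internal[rng.integers(0, len(internal))]
        return [p for p in parts if p != drop]
    if event == 1:  # alternative 5'/3' splice site via exon truncation
        if not base_positions:
            return None
        target = base_positions[rng.integers(0, len(base_positions))]
        seq = part_seqs[target]
        max_cut = len(seq) - min_exon
        if max_cut < 30:
            return None
        cut = int(rng.integers(30, max_cut + 1))
        from_start = bool(rng.integers(0, 2))
        # the truncated boundary must face a splice junction, otherwise the
        # variant is a bare substring of its parent (indistinguishable from
        # reads): trimming the start requires an upstream exon, trimming the
        # end a downstream one
        if from_start and parts.index(target) == 0:
            from_start = False
        if not from_start and parts.index(target) == len(parts) - 1:
            if parts.index(target) == 0:
                return None
            from_start = True
        new_seq = seq[cut:] if from_start else seq[: len(seq) - cut]
        key = (target[0], 2, cut * 2 + int(from_start))
        part_seqs.setdefault(key, new_seq)
        return [key if p == target else p for p in parts]
    # intron retention: merge two adjacent base exons with a retained intron
    adjacent = [
        (parts[j], parts[j + 1])
        for j in range(len(parts) - 1)
        if parts[j][1] == 1 and parts[j + 1][1] == 1
        and parts[j + 1][0] == parts[j][0] + 1
    ]
    if not adjacent:
        return None
    a, b = adjacent[rng.integers(0, len(adjacent))]
    key = (a[0], 3)
    if key not in part_seqs:
        intron = random_dna(int(rng.integers(100, 301)), rng)
        part_seqs[key] = part_seqs[a] + intron + part_seqs[b]
    out = []
    for p in parts:
        if p == a:
            out.append(key)
        elif p == b:
            continue
        else:
            out.append(p)
    return out


def simulate_transcriptome(
    n_genes: int = 20,
    isoform_dist: dict[int, float] | None = None,
    exon_len_range: tuple[int, int] = (300, 800),
    fpkm_range: tuple[float, float] = (2.0, 200.0),
    rng: np.random.Generator | None = None,
    n_exons_range: tuple[int, int] = (3, 7),
    zero_fraction: float = 0.1,
    min_exon: int = 100,
) -> list[SimulatedGene]:
    """Generate ground-truth genes with alternatively spliced isoforms.

    ``isoform_dist`` maps isoform count to probability (default uniform over
    1..5).  FPKM is log-uniform over ``fpkm_range`` with ``zero_fraction`` of
    isoforms set to 0 (structure present, no reads — unexpressed).
    """
    if rng is None:
        rng = np.random.default_rng()
    if isoform_dist is None:
        isoform_dist = {n: 0.2 for n in range(1, 6)}
    ks = sorted(isoform_dist)
    probs = np.array([isoform_dist[k] for k in ks], dtype=float)
    probs /= probs.sum()
    genes: list[SimulatedGene] = []
    for gi in range(n_genes):
        n_iso = int(rng.choice(ks, p=probs))
        n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        part_seqs: dict[tuple, str] = {}
        for ei in range(n_exons):
            part_seqs[(ei, 1)] = random_dna(
                int(rng.integers(exon_len_range[0], exon_len_range[1] + 1)), rng
            )
        base = [(ei, 1) for ei in range(n_exons)]
        isoforms: list[list[tuple]] = [base]
        attempts = 0
        while len(isoforms) < n_iso and attempts < 50 * n_iso:
            attempts += 1
            parent = isoforms[int(rng.integers(0, len(isoforms)))]
            child = _apply_event(parent, part_seqs, exon_len_range, min_exon, rng)
            if child is None or child in isoforms or len(child) == 0:
                continue
            isoforms.append(child)
        # linearize: distinct parts in genomic order become the exon list
        parts_used = sorted({p for iso in isoforms for p in iso})
        index_of = {p: i for i, p in enumerate(parts_used)}
        exon_list = [part_seqs[p] for p in parts_used]
        iso_idx = [[index_of[p] for p in iso] for iso in isoforms]
        lo, hi = fpkm_range
        fpkms = []
        for _ in isoforms:
            if rng.random() < zero_fraction:
                fpkms.append(0.0)
            else:
                fpkms.append(float(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        genes.append(
            SimulatedGene(
                gene_id=f"g{gi + 1:03d}",
                exons=exon_list,
                isoforms=iso_idx,
                fpkm=fpkms,
            )
        )
    return genes


@dataclass
class ReadSimResult:
    """Reads plus ground truth from one simulation."""

    pairs: list[ReadPair]
    truth: pd.DataFrame  # per isoform: ids, lengths, requested/realized FPKM
    fragment_origin: dict[str, str]  # fragment_id -> isoform_id


def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n = len(seq)
    n_err = rng.binomial(n, error_rate)
    if n_err == 0:
        return seq
    positions = rng.choice(n, size=n_err, replace=False)
    arr = bytearray(seq, "ascii")
    for p in positions:
        current = chr(arr[p])
        choices = [b for b in "ACGT" if b != current]
        arr[p] = ord(choices[rng.integers(0, 3)])
    return arr.decode()


def simulate_reads(
    genes: Sequence[SimulatedGene],
    read_len: int = 100,
    frag_mu: float = 250.0,
    frag_sd: float = 25.0,
    depth: float = 25.0,
    total_fragments: int | None = None,
    error_rate: float = 0.0,
    stranded: bool = True,
    rng: np.random.Generator | None = None,
) -> ReadSimResult:
    """Simulate paired-end fragments from expressed isoforms.

    Fragment counts are multinomial with weights FPKM x length; ``depth`` is
    mean coverage (total sequenced bases / total expressed transcript bases)
    and sets the library size unless ``total_fragments`` is given.  Fragment
    lengths are Gaussian, clamped to [read_len, isoform length]; mate 1 reads
    the fragment start forward, mate 2 the fragment end reverse-complemented
    (orientation randomized per fragment for unstranded libraries).
    """
    if rng is None:
        rng = np.random.default_rng()
    if frag_mu < read_len:
        raise ValueError("mean fragment length must be >= read length")
    iso_ids: list[str] = []
    iso_seqs: list[str] = []
    iso_fpkm: list[float] = []
    iso_gene: list[str] = []
    for gene in genes:
        for i in range(len(gene.isoforms)):
            seq = gene.isoform_sequence(i)
            if gene.fpkm[i] > 0 and len(seq) < read_len:
                logger.warning(
                    "%s shorter than read length; skipped", gene.isoform_id(i)
                )
                continue
            iso_ids.append(gene.isoform_id(i))
            iso_seqs.append(seq)
            iso_fpkm.append(gene.fpkm[i])
            iso_gene.append(gene.gene_id)
    weights = np.array(
        [f * len(s) for f, s in zip(iso_fpkm, iso_seqs)], dtype=float
    )
    expressed_len = sum(len(s) for f, s in zip(iso_fpkm, iso_seqs) if f > 0)
    if total_fragments is None:
        total_fragments = int(round(depth * expressed_len / (2 * read_len)))
    if weights.sum() > 0 and total_fragments > 0:
        counts = rng.multinomial(total_fragments, weights / weights.sum())
    else:
        counts = np.zeros(len(iso_ids), dtype=int)
    pairs: list[ReadPair] = []
    origin: dict[str, str] = {}
    frag_no = 0
    for ii, n_frags in enumerate(counts):
        seq = iso_seqs[ii]
        L = len(seq)
        if n_frags == 0:
            continue
        flens = rng.normal(frag_mu, frag_sd, size=n_frags)
        flens = np.clip(np.rint(flens).astype(int), read_len, L)
        for fl in flens:
            start = int(rng.integers(0, L - fl + 1))
            frag = seq[start : start + fl]
            mate1 = frag[:read_len]
            mate2 = reverse_complement(frag[-read_len:])
            if not stranded and rng.random() < 0.5:
                mate1, mate2 = mate2, mate1
            mate1 = _add_errors(mate1, error_rate, rng)
            mate2 = _add_errors(mate2, error_rate, rng)
            fid = f"frag{frag_no:07d}"
            frag_no += 1
            pairs.append(ReadPair(fid, mate1, mate2, stranded))
            origin[fid] = iso_ids[ii]
    # realized FPKM on the requested scale: proportional to fragments per
    # kilobase, normalized so the FPKM mass of the library is preserved
    # (E[realized] = requested for every isoform)
    total = max(1, int(counts.sum()))
    mass = float(weights.sum())  # sum of fpkm * length
    realized = [
        (c / (len(s) / 1000.0)) * (mass / 1000.0) / total if total else 0.0
        for c, s in zip(counts, iso_seqs)
    ]
    truth = pd.DataFrame(
        {
            "isoform_id": iso_ids,
            "gene_id": iso_gene,
            "length": [len(s) for s in iso_seqs],
            "fpkm_requested": iso_fpkm,
            "fpkm_realized": realized,
            "fragments": counts,
        }
    )
    return ReadSimResult(pairs=pairs, truth=truth, fragment_origin=origin)


def reference_sequences(genes: Sequence[SimulatedGene]) -> dict[str, str]:
    """isoform_id -> sequence for every isoform (expressed or not)."""
    out = {}
    for gene in genes:
        for i in range(len(gene.isoforms)):
            out[gene.isoform_id(i)] = gene.isoform_sequence(i)
    return out


def write_simulation(
    genes: Sequence[SimulatedGene],
    result: ReadSimResult,
    outdir: str | Path,
) -> None:
    """Write reference FASTA, truth TSV and paired FASTQ files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta_sequences(reference_sequences(genes), outdir / "reference.fasta")
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "reads_1.fastq", "w") as f1, open(
        outdir / "reads_2.fastq", "w"
    ) as f2:
        for pair in result.pairs:
            f1.write(
                f"@{pair.fragment_id}/1\n{pair.mate1}\n+\n{'I' * len(pair.mate1)}\n"
            )
            f2.write(
                f"@{pair.fragment_id}/2\n{pair.mate2}\n+\n{'I' * len(pair.mate2)}\n"
            )
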