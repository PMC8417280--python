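"""Assembly scoring: transcript matching, precision/recall/F-score, strata.

An assembled transcript is *correct* when at least 90% of its sequence
overlaps at least 80% of an expressed reference transcript.  Overlap is
computed by chaining exact k-mer matches co-linearly on both strands —
lossless here because synthetic sequences are uniform-random and thus
effectively unique, so chained exact matching recovers the same overlap
an aligner would report.

precision = correct assemblies / all assemblies,
recall    = matched references / expressed references,
Fscore    = 2 * precision * recall / (precision + recall).

Expressed means realized FPKM > 1.  Strata recompute the metrics per
gene-isoform-count bin {1,2,3,4,>4} and per FPKM bin {(1,10], (10,50],
(50,inf)}.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import pandas as pd

from .io import reverse_complement

ASSEMBLED_COVERAGE_MIN = 0.9
REFERENCE_COVERAGE_MIN = 0.8
EXPRESSED_FPKM_MIN = 1.0

FPKM_BINS = (("(1,10]", 1.0, 10.0), ("(10,50]", 10.0, 50.0), ("(50,inf)", 50.0, float("inf")))
ISOFORM_BINS = ("1", "2", "3", "4", ">4")


@dataclass
class MatchResult:
    """Best-reference overlap for one assembled transcript."""

    assembled_id: str
    matched_reference_id: str | None
    assembled_coverage_fraction: float
    reference_coverage_fraction: float
    best_reference_id: str | None = None


@dataclass
class EvalReport:
    precision: float
    recall: float
    fscore: float
    n_assembled: int = 0
    n_matched: int = 0
    n_reference: int = 0
    n_reference_matched: int = 0
    flags: list[str] = field(default_factory=list)
    strata: dict = field(default_factory=dict)


def fscore(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _chain_coverage(anchors: list[tuple[int, int]], k: int) -> tuple[int, int]:
    """Covered bases (on assembled, on reference) of the best co-linear chain.

    Anchors are exact k-mer matches (apos, rpos).  The chain maximizes the
    number of anchors increasing strictly in both coordinates (longest
    increasing subsequence), then coverage counts union lengths along it.
    """
    if not anchors:
        return 0, 0
    anchors.sort(key=lambda ar: (ar[0], -ar[1]))
    # patience LIS on rpos, strictly increasing
    tails: list[int] = []
    back: list[int] = []
    tail_idx: list[int] = []
    for i, (_a, r) in enumerate(anchors):
        j = bisect_left(tails, r)
        if j == len(tails):
            tails.append(r)
            tail_idx.append(i)
        else:
            tails[j] = r
            tail_idx[j] = i
        back.append(tail_idx[j - 1] if j > 0 else -1)
    # reconstruct
    chain = []
    cur = tail_idx[len(tails) - 1]
    while cur != -1:
        chain.append(anchors[cur])
        cur = back[cur]
    chain.reverse()
    cov_a = cov_r = 0
    prev_a = prev_r = None
    for a, r in chain:
        cov_a += k if prev_a is None else min(k, a - prev_a)
        cov_r += k if prev_r is None else min(k, r - prev_r)
        prev_a, prev_r = a, r
    return cov_a, cov_r


def match_transcripts(
    assembled: dict[str, str],
    reference: dict[str, str],
    expressed_ids: set[str],
    k: int = 25,
) -> list[MatchResult]:
    """Best expressed reference for each assembled transcript, 90/80 rule.

    Each assembly matches at most one reference (the one with the best
    overlap fractions, ties broken by reference id); one reference may be
    matched by several assemblies.
    """
    ref_index: dict[str, list[tuple[str, int]]] = {}
    for rid in sorted(expressed_ids & reference.keys()):
        seq = reference[rid]
        for i in range(len(seq) - k + 1):
            ref_index.setdefault(seq[i : i + k], []).append((rid, i))
    results = []
    for aid in sorted(assembled):
        aseq = assembled[aid]
        best = None  # (acov, rcov, rid, afrac, rfrac)
        for oriented in (aseq, reverse_complement(aseq)):
            per_ref: dict[str, list[tuple[int, int]]] = {}
            for i in range(len(oriented) - k + 1):
                for rid, rpos in ref_index.get(oriented[i : i + k], ()):
                    per_ref.setdefault(rid, []).append((i, rpos))
            for rid in sorted(per_ref):
                cov_a, cov_r = _chain_coverage(per_ref[rid], k)
                afrac = cov_a / len(aseq) if aseq else 0.0
                rfrac = cov_r / len(reference[rid])
                cand = (afrac, rfrac, rid)
                if best is None or (cand[0], cand[1]) > (best[0], best[1]) or (
                    (cand[0], cand[1]) == (best[0], best[1]) and rid < best[2]
                ):
                    best = cand
        if best is None:
            results.append(MatchResult(aid, None, 0.0, 0.0, None))
            continue
        afrac, rfrac, rid = best
        matched = afrac >= ASSEMBLED_COVERAGE_MIN and rfrac >= REFERENCE_COVERAGE_MIN
        results.append(
            MatchResult(
                assembled_id=aid,
                matched_reference_id=rid if matched else None,
                assembled_coverage_fraction=afrac,
                reference_coverage_fraction=rfrac,
                best_reference_id=rid,
            )
        )
    return results


def compute_metrics(
    matches: list[MatchResult],
    n_assembled: int,
    n_expressed_reference: int,
) -> EvalReport:
    """Overall precision/recall/F-score from match results."""
    n_matched = sum(1 for m in matches if m.matched_reference_id is not None)
    matched_refs = {m.matched_reference_id for m in matches if m.matched_reference_id}
    flags = []
    if n_assembled == 0:
        precision = 0.0
        flags.append("zero_assembled")
    else:
        precision = n_matched / n_assembled
    if n_expressed_reference == 0:
        recall = 0.0
        flags.append("zero_reference")
    else:
        recall = len(matched_refs) / n_expressed_reference
    return EvalReport(
        precision=precision,
        recall=recall,
        fscore=fscore(precision, recall),
        n_assembled=n_assembled,
        n_matched=n_matched,
        n_reference=n_expressed_reference,
        n_reference_matched=len(matched_refs),
        flags=flags,
    )


def _isoform_bin(n: int) -> str:
    return str(n) if n <= 4 else ">4"


def _fpkm_bin(f: float) -> str | None:
    for name, lo, hi in FPKM_BINS:
        if lo < f <= hi:
            return name
    return None


def stratify(matches: list[MatchResult], truth: pd.DataFrame) -> dict:
    """Per-stratum metrics keyed by gene isoform-count bin and FPKM bin.

    A reference transcript's isoform bin counts the *expressed* isoforms of
    its gene.  Precision within a stratum is computed over assemblies whose
    best reference falls in the stratum; empty strata are omitted.
    """
    expressed = truth[truth["fpkm_realized"] > EXPRESSED_FPKM_MIN]
    per_gene = expressed.groupby("gene_id")["isoform_id"].count()
    ref_iso_bin = {
        row.isoform_id: _isoform_bin(int(per_gene[row.gene_id]))
        for row in expressed.itertuples()
    }
    ref_fpkm_bin = {
        row.isoform_id: _fpkm_bin(float(row.fpkm_realized))
        for row in expressed.itertuples()
    }

    def metrics_for(ref_ids: set[str]) -> EvalReport | None:
        if not ref_ids:
            return None
        sub = [m for m in matches if m.best_reference_id in ref_ids]
        restricted = [
            MatchResult(
                m.assembled_id,
                m.matched_reference_id if m.matched_reference_id in ref_ids else None,
                m.assembled_coverage_fraction,
                m.reference_coverage_fraction,
                m.best_reference_id,
            )
            for m in sub
        ]
        return compute_metrics(restricted, len(sub), len(ref_ids))

    strata: dict = {"isoforms": {}, "fpkm": {}}
    for bin_name in ISOFORM_BINS:
        refs = {r for r, b in ref_iso_bin.items() if b == bin_name}
        rep = metrics_for(refs)
        if rep is not None:
            strata["isoforms"][bin_name] = rep
    for bin_name, _lo, _hi in FPKM_BINS:
        refs = {r for r, b in ref_fpkm_bin.items() if b == bin_name}
        rep = metrics_for(refs)
        if rep is not None:
            strata["fpkm"][bin_name] = rep
    return strata


def evaluate_assembly(
    assembled: dict[str, str],
    reference: dict[str, str],
    truth: pd.DataFrame,
    k: int = 25,
) -> EvalReport:
    """Full evaluation: match, overall metrics, strata."""
    expressed_ids = set(
        truth.loc[truth["fpkm_realized"] > EXPRESSED_FPKM_MIN, "isoform_id"]
    )
    matches = match_transcripts(assembled, reference, expressed_ids, k=k)
    report = compute_metrics(matches, len(assembled), len(expressed_ids))
    report.strata = stratify(matches, truth)
    return report


def report_to_dict(report: EvalReport) -> dict:
    """JSON-serializable view of an :class:`EvalReport` (nested strata too)."""
    out = {
        "precision": report.precision,
        "recall": report.recall,
        "fscore": report.fscore,
        "n_assembled": report.n_assembled,
        "n_matched": report.n_matched,
        "n_reference": report.n_reference,
        "n_reference_matched": report.n_reference_matched,
        "flags": report.flags,
    }
    if report.strata:
        out["strata"] = {
            axis: {name: report_to_dict(rep) for name, rep in bins.items()}
            for axis, bins in report.strata.items()
        }
    return out
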