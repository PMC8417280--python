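"""Assembly scoring: 90/80 matching rule, metrics, stratification."""

import numpy as np
import pandas as pd
import pytest

from splicebayes.evaluate import (
    MatchResult,
    compute_metrics,
    evaluate_assembly,
    fscore,
    match_transcripts,
    stratify,
)
from splicebayes.io import reverse_complement
from splicebayes.simulate import random_dna


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(50)
    return {f"r{i}": random_dna(2000, rng) for i in range(4)}


class TestMatching:
    def test_exact_copy_full_fractions(self, refs):
        (m,) = match_transcripts({"a0": refs["r0"]}, refs, set(refs))
        assert m.matched_reference_id == "r0"
        assert m.assembled_coverage_fraction == pytest.approx(1.0)
        assert m.reference_coverage_fraction == pytest.approx(1.0)

    def test_85_percent_prefix_matches(self, refs):
        (m,) = match_transcripts({"a0": refs["r1"][:1700]}, refs, set(refs))
        assert m.assembled_coverage_fraction == pytest.approx(1.0)
        assert m.reference_coverage_fraction == pytest.approx(0.85, abs=0.01)
        assert m.matched_reference_id == "r1"

    def test_79_percent_reference_coverage_fails(self, refs):
        (m,) = match_transcripts({"a0": refs["r1"][:1575]}, refs, set(refs))
        assert m.reference_coverage_fraction < 0.8
        assert m.matched_reference_id is None
        assert m.best_reference_id == "r1"

    def test_reverse_complement_orientation_matches(self, refs):
        (m,) = match_transcripts(
            {"a0": reverse_complement(refs["r2"])}, refs, set(refs)
        )
        assert m.matched_reference_id == "r2"

    def test_unexpressed_reference_not_matchable(self, refs):
        (m,) = match_transcripts({"a0": refs["r0"]}, refs, {"r1", "r2"})
        assert m.matched_reference_id is None

    def test_empty_reference_all_unmatched(self):
        (m,) = match_transcripts({"a0": "ACGT" * 100}, {}, set())
        assert m.matched_reference_id is None
        assert m.assembled_coverage_fraction == 0.0

    def test_exon_skip_sibling_still_matches(self, refs):
        # assembled lacking a short internal block still passes 90/80 when
        # the block is < 10% of the assembly: chained matching spans the gap
        rng = np.random.default_rng(51)
        a, b, c = random_dna(1200, rng), random_dna(150, rng), random_dna(1200, rng)
        reference = {"r": a + b + c}
        (m,) = match_transcripts({"skip": a + c}, reference, {"r"})
        assert m.assembled_coverage_fraction == pytest.approx(1.0, abs=0.02)
        assert m.reference_coverage_fraction == pytest.approx(
            2400 / 2550, abs=0.02
        )
        assert m.matched_reference_id == "r"


class TestMetrics:
    def test_fscore_symmetric_point(self):
        assert fscore(0.5, 0.5) == pytest.approx(0.5)

    def test_fscore_zero_recall(self):
        assert fscore(1.0, 0.0) == 0.0
        assert fscore(0.0, 0.0) == 0.0

    def test_fscore_plug_in(self):
        assert fscore(0.4, 0.6) == pytest.approx(0.48)

    def test_counts(self):
        matches = [
            MatchResult("a0", "r0", 1.0, 1.0),
            MatchResult("a1", "r0", 0.95, 0.9),
            MatchResult("a2", None, 1.0, 0.4),
        ]
        rep = compute_metrics(matches, n_assembled=3, n_expressed_reference=4)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(1 / 4)  # one distinct reference
        assert rep.fscore == pytest.approx(fscore(2 / 3, 1 / 4))

    def test_zero_denominators_flagged(self):
        rep = compute_metrics([], 0, 0)
        assert rep.precision == 0.0
        assert rep.recall == 0.0
        assert set(rep.flags) == {"zero_assembled", "zero_reference"}


def _truth(rows):
    return pd.DataFrame(
        rows, columns=["isoform_id", "gene_id", "length", "fpkm_realized"]
    )


class TestStratify:
    def test_single_isoform_genes_only_bin_one(self):
        truth = _truth(
            [("g1.i1", "g1", 1000, 20.0), ("g2.i1", "g2", 1000, 5.0)]
        )
        matches = [MatchResult("a0", "g1.i1", 1.0, 1.0, "g1.i1")]
        strata = stratify(matches, truth)
        assert set(strata["isoforms"]) == {"1"}

    def test_five_isoform_gene_lands_in_gt4_bin(self):
        rows = [(f"g1.i{j}", "g1", 1000, 15.0) for j in range(1, 6)]
        strata = stratify([], _truth(rows))
        assert set(strata["isoforms"]) == {">4"}

    def test_fpkm_30_in_10_50_bin(self):
        truth = _truth([("g1.i1", "g1", 1000, 30.0)])
        strata = stratify([], truth)
        assert set(strata["fpkm"]) == {"(10,50]"}

    def test_empty_bins_omitted_and_counts_aggregate(self):
        truth = _truth(
            [
                ("g1.i1", "g1", 1000, 30.0),
                ("g2.i1", "g2", 1000, 5.0),
                ("g2.i2", "g2", 1000, 120.0),
            ]
        )
        matches = [
            MatchResult("a0", "g1.i1", 1.0, 1.0, "g1.i1"),
            MatchResult("a1", "g2.i2", 1.0, 1.0, "g2.i2"),
        ]
        strata = stratify(matches, truth)
        assert set(strata["isoforms"]) == {"1", "2"}
        pooled = sum(rep.n_matched for rep in strata["isoforms"].values())
        assert pooled == 2


class TestEndToEnd:
    def test_self_match_identity(self):
        rng = np.random.default_rng(60)
        refs = {f"r{i}": random_dna(1500, rng) for i in range(5)}
        truth = _truth([(r, f"g{i}", 1500, 50.0) for i, r in enumerate(refs)])
        rep = evaluate_assembly(dict(refs), refs, truth)
        assert rep.precision == 1.0
        assert rep.recall == 1.0
        assert rep.fscore == 1.0

    def test_added_junk_lowers_precision_not_recall(self):
        rng = np.random.default_rng(61)
        refs = {f"r{i}": random_dna(1500, rng) for i in range(3)}
        truth = _truth([(r, f"g{i}", 1500, 50.0) for i, r in enumerate(refs)])
        base = evaluate_assembly(dict(refs), refs, truth)
        with_junk = evaluate_assembly(
            {**refs, "junk": random_dna(900, rng)}, refs, truth
        )
        assert with_junk.precision < base.precision
        assert with_junk.recall == base.recall
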