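"""Fragment likelihoods and the Bayesian transcript caller."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln

from splicebayes.candidates import CandidateTranscript
from splicebayes.graph import ReadIndex, build_all_graphs
from splicebayes.io import ReadPair, reverse_complement
from splicebayes.kmers import build_kmer_table, filter_errors
from splicebayes.model import (
    FragmentLengthDist,
    GibbsConfig,
    call_transcripts,
    fragment_likelihood,
    likelihood_matrix,
    run_gibbs,
)
from splicebayes.simulate import random_dna

from conftest import K, tile_pairs


def brute_posterior(L, pi=0.5, alpha=1.0):
    """Exact posterior over indicator states by full enumeration (oracle)."""
    n, m = L.shape
    mass = {}
    for c in itertools.product([0, 1], repeat=m):
        S = [t for t in range(m) if c[t]]
        base = sum(math.log(pi) if x else math.log(1 - pi) for x in c)
        options = []
        ok = True
        for r in range(n):
            opts = [t for t in S if L[r, t] > 0]
            if not opts:
                ok = False
                break
            options.append(opts)
        if not ok:
            continue
        total = 0.0
        for z in itertools.product(*options) if n else [()]:
            counts = [list(z).count(t) for t in S]
            dm = (
                gammaln(alpha * len(S))
                - gammaln(alpha * len(S) + n)
                + sum(gammaln(alpha + cc) for cc in counts)
                - len(S) * gammaln(alpha)
            ) if S else 0.0
            ll = sum(math.log(L[r, z[r]]) for r in range(n))
            total += math.exp(base + dm + ll)
        mass[c] = total
    norm = sum(mass.values())
    return {c: v / norm for c, v in mass.items()}


def _pair_from(seq, start, flen, read_len=100, fid="f"):
    frag = seq[start : start + flen]
    return ReadPair(fid, frag[:read_len], reverse_complement(frag[-read_len:]))


class TestFragmentLikelihood:
    def setup_method(self):
        rng = np.random.default_rng(21)
        self.a = random_dna(600, rng)
        self.b = random_dna(500, rng)
        self.c = random_dna(600, rng)
        self.incl = self.a + self.b + self.c
        self.skip = self.a + self.c
        self.fl = FragmentLengthDist(mean=250, sd=25, lo=K, hi=600)

    def _cand(self, seq, eff=None):
        return CandidateTranscript(
            path=("n",), sequence=seq, effective_length=eff or max(1, len(seq) - 249)
        )

    def test_incompatible_fragment_zero(self):
        frag = _pair_from(self.b, 100, 250)  # inside the cassette exon
        assert fragment_likelihood(frag, self._cand(self.skip), self.fl) == 0.0

    def test_unique_placement_mode_length(self):
        cand = self._cand(self.incl, eff=1000.0)
        frag = _pair_from(self.incl, 400, 250)
        val = fragment_likelihood(frag, cand, self.fl)
        assert val == pytest.approx(self.fl.pmf(250) / 1000.0)

    def test_effective_length_ratio_two_to_one(self):
        frag = _pair_from(self.incl, 100, 250)
        short = self._cand(self.incl, eff=500.0)
        long = self._cand(self.incl, eff=1000.0)
        v_short = fragment_likelihood(frag, short, self.fl)
        v_long = fragment_likelihood(frag, long, self.fl)
        assert v_short == pytest.approx(2.0 * v_long)

    def test_junction_overhang_rejected(self):
        # mate spanning the skip junction must not place on the inclusion
        # isoform even though its flanking k-mers occur there
        frag = _pair_from(self.skip, 520, 250)
        assert fragment_likelihood(frag, self._cand(self.incl), self.fl) == 0.0
        assert fragment_likelihood(frag, self._cand(self.skip), self.fl) > 0.0

    def test_mismatch_budget_tolerates_errors(self):
        frag = _pair_from(self.incl, 300, 250)
        mutated = "T" + frag.mate1[1:] if frag.mate1[0] != "T" else "A" + frag.mate1[1:]
        noisy = ReadPair("f", mutated, frag.mate2)
        assert fragment_likelihood(noisy, self._cand(self.incl), self.fl) > 0.0


class TestSampler:
    def test_single_candidate_degenerate(self):
        rng = np.random.default_rng(31)
        seq = random_dna(600, rng)
        pairs = tile_pairs(seq, step=25)
        table = filter_errors(build_kmer_table(pairs, K))
        (graph,) = build_all_graphs(table, ReadIndex(pairs, K))
        cand = CandidateTranscript(
            path=tuple(graph.nodes), sequence=seq, effective_length=351.0
        )
        called, summary = call_transcripts(
            graph, [cand], pairs, GibbsConfig(sweeps=10, burn_in=2),
            np.random.default_rng(0),
        )
        assert summary.expression_prob[0] == 1.0
        assert summary.mean_abundance[0] == 1.0
        assert len(called) == 1

    def test_mixture_recovery_70_30(self):
        # 1000 fragments, 20% ambiguous, rest split 70/30
        p = 1e-4
        L = np.vstack(
            [np.tile([p, 0.0], (560, 1)),
             np.tile([0.0, p], (240, 1)),
             np.tile([p, p], (200, 1))]
        )
        for seed in range(3):
            summ = run_gibbs(
                L, GibbsConfig(sweeps=800, burn_in=200), np.random.default_rng(seed)
            )
            assert summ.mean_abundance[0] == pytest.approx(0.7, abs=0.05)
            assert summ.mean_abundance[1] == pytest.approx(0.3, abs=0.05)

    def test_decoy_without_unique_support_suppressed(self):
        p = 1e-4
        L = np.vstack(
            [np.tile([p, 0.0], (60, 1)), np.tile([p, p], (40, 1))]
        )
        below = 0
        for seed in range(10):
            summ = run_gibbs(
                L, GibbsConfig(sweeps=600, burn_in=200), np.random.default_rng(seed)
            )
            below += summ.expression_prob[1] < 0.5
        assert below >= 9

    def test_matches_enumeration_three_candidates(self):
        L = np.array(
            [
                [2e-4, 0.0, 1e-4],
                [2e-4, 1e-4, 0.0],
                [0.0, 1e-4, 1e-4],
                [2e-4, 1e-4, 1e-4],
                [2e-4, 0.0, 1e-4],
            ]
        )
        exact = brute_posterior(L)
        marg = [sum(v for c, v in exact.items() if c[t]) for t in range(3)]
        summ = run_gibbs(
            L, GibbsConfig(sweeps=6000, burn_in=1000), np.random.default_rng(2)
        )
        for t in range(3):
            assert summ.expression_prob[t] == pytest.approx(marg[t], abs=0.04)

    def test_label_invariance(self):
        L = np.array(
            [
                [2e-4, 0.0, 1e-4],
                [2e-4, 1e-4, 0.0],
                [0.0, 1e-4, 1e-4],
                [2e-4, 1e-4, 1e-4],
            ]
        )
        perm = [2, 0, 1]
        cfg = GibbsConfig(sweeps=6000, burn_in=1000)
        base = run_gibbs(L, cfg, np.random.default_rng(5)).expression_prob
        permuted = run_gibbs(L[:, perm], cfg, np.random.default_rng(6)).expression_prob
        for j, t in enumerate(perm):
            assert permuted[j] == pytest.approx(base[t], abs=0.05)

    def test_no_nan_under_underflow(self):
        L = np.array([[1e-280, 1e-290], [1e-285, 1e-280], [1e-280, 1e-280]])
        summ = run_gibbs(
            L, GibbsConfig(sweeps=200, burn_in=50), np.random.default_rng(0)
        )
        assert np.isfinite(summ.expression_prob).all()
        assert np.isfinite(summ.mean_abundance).all()


class TestCallTranscripts:
    def _toy_setup(self, isoform_subset=None):
        from splicebayes.candidates import enumerate_candidates

        rng = np.random.default_rng(41)
        left = random_dna(600, rng)
        cass = random_dna(400, rng)
        right = random_dna(600, rng)
        incl, skip = left + cass + right, left + right
        sources = [incl, skip] if isoform_subset is None else isoform_subset
        pairs = tile_pairs(sources, step=20)
        table = filter_errors(build_kmer_table(pairs, K))
        (graph,) = build_all_graphs(table, ReadIndex(pairs, K))
        cands = enumerate_candidates(graph, 100)
        return graph, cands, pairs, (incl, skip)

    def test_both_isoforms_called_on_cassette_toy(self):
        graph, cands, pairs, isoforms = self._toy_setup()
        called, summary = call_transcripts(
            graph, cands, pairs,
            GibbsConfig(sweeps=400, burn_in=100), np.random.default_rng(1),
        )
        assert {t.sequence for t in called} == set(isoforms)
        assert sum(t.abundance for t in called) == pytest.approx(1.0)

    def test_skip_only_reads_call_only_skip(self):
        rng = np.random.default_rng(41)
        left = random_dna(600, rng)
        _cass = random_dna(400, rng)
        right = random_dna(600, rng)
        skip = left + right
        graph, cands, pairs, _ = self._toy_setup(isoform_subset=[skip])
        called, _summary = call_transcripts(
            graph, cands, pairs,
            GibbsConfig(sweeps=200, burn_in=50), np.random.default_rng(1),
        )
        assert [t.sequence for t in called] == [skip]

    def test_zero_fragments_empty_call_with_warning(self, caplog):
        graph, cands, _pairs, _iso = self._toy_setup()
        graph.compat.clear()
        import logging

        with caplog.at_level(logging.WARNING, logger="splicebayes.model"):
            called, summary = call_transcripts(
                graph, cands, [], GibbsConfig(sweeps=10, burn_in=2),
                np.random.default_rng(0),
            )
        assert called == []
        assert summary.n_fragments == 0
        assert "unexplainable" in caplog.text
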