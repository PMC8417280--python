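"""Bayesian transcript calling from candidate paths by Gibbs sampling.

The generative model per splicing graph, over n candidate transcripts and
N sequenced fragments:

* ``c_t ~ Bernoulli(pi)`` iid — hidden indicator that candidate t is
  expressed (default pi = 0.5, the indifferent prior);
* ``e | c ~ Dirichlet(alpha)`` on the simplex restricted to expressed
  candidates (default alpha = 1, flat);
* ``z_r | e ~ Categorical(e)`` — the transcript fragment r came from;
* fragment r given ``z_r = t`` is observed with probability ``L(r, t)``:
  the fragment-length probability of every admissible placement of the
  mate pair on t, divided by t's effective length.

Because expression enters through the indicator rather than through a
minimum-abundance rule, poorly expressed transcripts that own even a few
uniquely assigned fragments are retained: an indicator can only switch
off while no fragment is assigned to it.

The sampler targets the abundance-marginalized joint p(c, z): assignments
are refreshed by data augmentation (draw e | c, z, then z | c, e, discard
e), and each indicator is flipped by a Metropolis-Hastings birth/death
move whose proposal re-allocates every fragment compatible with the
candidate — so a redundant candidate can switch off even while fragments
currently sit on it, and a uniquely supported one is forced on because
the death of the last candidate explaining a fragment is always rejected.
Abundances for posterior summaries are drawn from their Dirichlet
conditional after each sweep.  Acceptance ratios are computed in log
space; no NaN is ever returned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .candidates import CandidateTranscript
from .graph import SplicingGraph
from .io import AssembledTranscript, ReadPair, reverse_complement
from .kmers import iter_kmers

logger = logging.getLogger(__name__)


@dataclass
class FragmentLengthDist:
    """Discretized Gaussian fragment-length distribution on [lo, hi]."""

    mean: float = 250.0
    sd: float = 25.0
    lo: int = 25
    hi: int = 1000

    def __post_init__(self) -> None:
        lengths = np.arange(self.lo, self.hi + 1)
        dens = norm.pdf(lengths, loc=self.mean, scale=self.sd)
        total = dens.sum()
        if total <= 0:  # degenerate window far from the mean
            dens = np.full_like(dens, 1.0 / len(dens))
            total = 1.0
        self._pmf = dens / total

    def pmf(self, length: int) -> float:
        if length < self.lo or length > self.hi:
            return 0.0
        return float(self._pmf[length - self.lo])


def estimate_flen_dist(
    lengths: Sequence[int],
    k: int,
    min_observations: int = 100,
    fallback: tuple[float, float] = (250.0, 25.0),
) -> FragmentLengthDist:
    """Empirical Gaussian fit of implied fragment lengths, truncated at
    [k, max observed]; falls back to the configured default when fewer than
    ``min_observations`` unique placements are available."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size < min_observations:
        mu, sd = fallback
        return FragmentLengthDist(mean=mu, sd=sd, lo=k, hi=int(mu + 6 * sd))
    mu = float(arr.mean())
    sd = float(arr.std(ddof=1))
    sd = max(sd, 1.0)
    return FragmentLengthDist(mean=mu, sd=sd, lo=k, hi=int(arr.max()))


@dataclass
class ModelState:
    """Gibbs state: indicators c, abundance simplex e, assignments z."""

    c: np.ndarray
    e: np.ndarray
    z: np.ndarray


@dataclass
class PosteriorSummary:
    """Posterior means over kept Gibbs samples, per candidate."""

    expression_prob: np.ndarray
    mean_abundance: np.ndarray
    n_samples: int
    burn_in: int
    n_fragments: int
    n_fragments_dropped: int = 0


# ---------------------------------------------------------------------------
# placement and likelihood


class _CandidateIndex:
    """k-mer -> positions within one candidate's sequence."""

    #: tolerated mismatch fraction when verifying a placement against the
    #: candidate sequence -- generous for substitution errors, far below the
    #: divergence of a mate overhanging a junction the candidate lacks
    max_mismatch_frac = 0.1

    def __init__(self, sequence: str, k: int) -> None:
        self.k = k
        self.sequence = sequence
        self.length = len(sequence)
        pos: dict[str, list[int]] = {}
        for i, km in enumerate(iter_kmers(sequence, k)):
            pos.setdefault(km, []).append(i)
        self.pos = pos

    def _verify(self, mate: str, s: int) -> bool:
        window = self.sequence[s : s + len(mate)]
        if window == mate:
            return True
        budget = int(self.max_mismatch_frac * len(mate))
        mism = 0
        for a, b in zip(mate, window):
            if a != b:
                mism += 1
                if mism > budget:
                    return False
        return True

    def mate_starts(self, mate: str) -> set[int] | None:
        """Start positions of ``mate`` on the candidate, or None when no
        placement survives verification.

        Candidate placements are anchored by the mate's k-mers found in the
        index; each is verified against the full mate sequence with a small
        mismatch budget, so a mate overhanging a splice junction absent from
        the candidate is rejected even though its flanking k-mers map.
        """
        k = self.k
        seen: set[int] = set()
        starts: set[int] = set()
        for off, km in enumerate(iter_kmers(mate, k)):
            hits = self.pos.get(km)
            if hits is None:
                continue
            for p in hits:
                s = p - off
                if s in seen:
                    continue
                seen.add(s)
                if s < 0 or s + len(mate) > self.length:
                    continue
                if self._verify(mate, s):
                    starts.add(s)
            if starts:
                # anchored and verified; later windows re-derive the same
                # placements (barring pathological repeats)
                break
        return starts or None


def fragment_likelihood(
    fragment: ReadPair,
    candidate: CandidateTranscript,
    flen_dist: FragmentLengthDist,
    cand_index: _CandidateIndex | None = None,
    stranded: bool = True,
) -> float:
    """Probability of observing a mate pair from a candidate transcript.

    Zero when incompatible; otherwise the sum over admissible placements of
    the fragment-length probability, divided by the candidate's effective
    length.  A placement puts mate 1 forward and the reverse complement of
    mate 2 downstream on the same strand (both orientations are tried for
    unstranded libraries).
    """
    if cand_index is None:
        cand_index = _CandidateIndex(candidate.sequence, flen_dist.lo)
    orientations = [(fragment.mate1, reverse_complement(fragment.mate2))]
    if not stranded:
        orientations.append(
            (fragment.mate2, reverse_complement(fragment.mate1))
        )
    total = 0.0
    for left, right in orientations:
        if not left or not right:
            continue
        starts = cand_index.mate_starts(left)
        if not starts:
            continue
        right_starts = cand_index.mate_starts(right)
        if not right_starts:
            continue
        for s in sorted(starts):
            for s2 in sorted(right_starts):
                flen = s2 + len(right) - s
                if flen <= 0:
                    continue
                total += flen_dist.pmf(flen)
    return total / candidate.effective_length


def likelihood_matrix(
    fragments: Sequence[ReadPair],
    candidates: Sequence[CandidateTranscript],
    flen_dist: FragmentLengthDist,
    k: int,
    stranded: bool = True,
) -> np.ndarray:
    """Dense (n_fragments x n_candidates) placement likelihood matrix."""
    indexes = [_CandidateIndex(c.sequence, k) for c in candidates]
    L = np.zeros((len(fragments), len(candidates)))
    for ri, frag in enumerate(fragments):
        for ti, (cand, idx) in enumerate(zip(candidates, indexes)):
            L[ri, ti] = fragment_likelihood(
                frag, cand, flen_dist, cand_index=idx, stranded=stranded
            )
    return L


# ---------------------------------------------------------------------------
# Gibbs sampler


@dataclass
class GibbsConfig:
    sweeps: int = 2000
    burn_in: int = 500
    pi: float = 0.5
    alpha: float = 1.0
    call_threshold: float = 0.5


def _sample_rows(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a non-negative weight matrix."""
    cum = np.cumsum(weights, axis=1)
    totals = cum[:, -1]
    u = rng.random(weights.shape[0]) * totals
    return (cum <= u[:, None]).sum(axis=1).clip(max=weights.shape[1] - 1)


def _log_dm(counts_on: np.ndarray, alpha: float) -> float:
    """log Dirichlet-multinomial mass of assignment counts over the
    expressed set (abundances integrated out analytically)."""
    m = counts_on.size
    if m == 0:
        return 0.0
    n = int(counts_on.sum())
    return float(
        gammaln(alpha * m)
        - gammaln(alpha * m + n)
        + gammaln(alpha + counts_on).sum()
        - m * gammaln(alpha)
    )


def _realloc_weights(
    L_sub: np.ndarray, counts: np.ndarray, cols: np.ndarray, alpha: float
) -> np.ndarray:
    """Proposal weights (alpha + n_s) * L(r, s) — a deterministic function
    of the discrete state, so forward and reverse densities are exact."""
    return L_sub * (alpha + counts[cols])[None, :]


def _toggle_candidate(
    t: int,
    c: np.ndarray,
    z: np.ndarray,
    L: np.ndarray,
    logL: np.ndarray,
    compat_rows: np.ndarray,
    config: GibbsConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Metropolis-Hastings birth/death move for one expression indicator.

    Proposes flipping c_t together with a re-allocation of every fragment
    compatible with t; the proposal draws assignments from count-weighted
    likelihoods of the proposed support and the acceptance ratio is taken
    against the abundance-marginalized joint (Dirichlet-multinomial), so a
    redundant candidate can switch off even while fragments currently sit
    on it.  Mutates c in place and returns the (possibly updated) z.
    """
    n_frags, n_cands = L.shape
    on = np.flatnonzero(c)
    rows = compat_rows
    alpha = config.alpha
    log_prior = math.log(config.pi) - math.log1p(-config.pi)
    counts = np.bincount(z, minlength=n_cands) if n_frags else np.zeros(
        n_cands, dtype=np.int64
    )

    if c[t] == 1:
        s_new = on[on != t]
        sign = -1.0
    else:
        s_new = np.sort(np.append(on, t))
        sign = 1.0

    if rows.size == 0 or s_new.size == 0:
        # no fragments to re-allocate: prior times Ockham factor only
        if s_new.size == 0 and n_frags > 0:
            return z  # last explaining candidate is forced on
        delta = (
            sign * log_prior
            + _log_dm(counts[s_new], alpha)
            - _log_dm(counts[on], alpha)
        )
        if math.log(max(rng.random(), 1e-300)) < delta:
            c[t] = 1 - c[t]
        return z

    # forward: re-allocate all compatible fragments over the new support
    W = _realloc_weights(L[np.ix_(rows, s_new)], counts, s_new, alpha)
    w_tot = W.sum(axis=1)
    if np.any(w_tot <= 0.0):
        # death move with a fragment only t can explain: forced on
        return z
    idx = _sample_rows(W, rng)
    z_new_vals = s_new[idx]
    log_q_fwd = float(
        np.log(W[np.arange(W.shape[0]), idx] / w_tot).sum()
    )
    z_prop = z.copy()
    z_prop[rows] = z_new_vals
    counts_prop = np.bincount(z_prop, minlength=n_cands)

    # reverse: re-allocation over the current support, weighted by the
    # proposed state's counts
    s_cur = on
    V = _realloc_weights(L[np.ix_(rows, s_cur)], counts_prop, s_cur, alpha)
    v_tot = V.sum(axis=1)
    pos = {int(sv): j for j, sv in enumerate(s_cur)}
    cur_idx = np.array([pos[int(z[r])] for r in rows])
    chosen = V[np.arange(V.shape[0]), cur_idx]
    if np.any(chosen <= 0.0) or np.any(v_tot <= 0.0):
        log_q_rev = -math.inf
    else:
        log_q_rev = float(np.log(chosen / v_tot).sum())

    delta = (
        sign * log_prior
        + _log_dm(counts_prop[s_new], alpha)
        - _log_dm(counts[on], alpha)
        + float(logL[rows, z_prop[rows]].sum())
        - float(logL[rows, z[rows]].sum())
        + log_q_rev
        - log_q_fwd
    )
    if math.log(max(rng.random(), 1e-300)) < delta:
        c[t] = 1 - c[t]
        return z_prop
    return z


def gibbs_sweep(
    state: ModelState,
    L: np.ndarray,
    config: GibbsConfig,
    rng: np.random.Generator,
    logL: np.ndarray | None = None,
    compat_cols: list[np.ndarray] | None = None,
    toggle_ts: Sequence[int] | None = None,
) -> ModelState:
    """One full sweep of the sampler on the abundance-marginalized model.

    (a) data augmentation for the assignments: draw e | c, z from its
    Dirichlet conditional, then z | c, e row-wise; (b) a birth/death
    toggle per indicator with the fragment re-allocation built into the
    proposal; (c) a fresh abundance draw e | c, z for posterior summaries.

    A fragment whose every compatible candidate is off cannot arise: the
    death move of the last candidate explaining it is always rejected,
    which is what forces uniquely supported candidates on.
    """
    n_frags, n_cands = L.shape
    if logL is None:
        with np.errstate(divide="ignore"):
            logL = np.log(L)
    if compat_cols is None:
        compat_cols = [np.flatnonzero(L[:, t] > 0) for t in range(n_cands)]
    c = state.c.copy()
    z = state.z

    def draw_e(counts: np.ndarray) -> np.ndarray:
        e = np.zeros(n_cands)
        on = c.astype(bool)
        if on.any():
            gam = rng.gamma(config.alpha + counts[on])
            gam = np.maximum(gam, 1e-300)
            e[on] = gam / gam.sum()
        return e

    # (a) assignments via augmentation
    counts = np.bincount(z, minlength=n_cands)
    e_aux = draw_e(counts)
    z = _sample_rows(L * e_aux[None, :], rng)
    # (b) indicator toggles (optionally a scheduled subset per sweep)
    if toggle_ts is None:
        toggle_ts = range(n_cands)
    for t in toggle_ts:
        z = _toggle_candidate(t, c, z, L, logL, compat_cols[t], config, rng)
    # (c) abundances for summaries
    counts = np.bincount(z, minlength=n_cands)
    e_new = draw_e(counts)
    return ModelState(c=c, e=e_new, z=z)


def run_gibbs(
    L: np.ndarray,
    config: GibbsConfig,
    rng: np.random.Generator,
    record_states: bool = False,
):
    """Run burn-in + sampling sweeps; return a :class:`PosteriorSummary`
    (optionally also the per-sweep indicator states for diagnostics)."""
    n_frags, n_cands = L.shape
    if n_frags == 0:
        raise ValueError("no fragments to sample over")
    c0 = np.ones(n_cands, dtype=np.int64)
    e0 = np.full(n_cands, 1.0 / n_cands)
    z0 = _sample_rows(L * e0[None, :], rng)
    state = ModelState(c=c0, e=e0, z=z0)
    c_sum = np.zeros(n_cands)
    e_sum = np.zeros(n_cands)
    kept = 0
    states = [] if record_states else None
    with np.errstate(divide="ignore"):
        logL = np.log(L)
    compat_cols = [np.flatnonzero(L[:, t] > 0) for t in range(n_cands)]
    # candidates owning a fragment no other candidate can explain are pinned
    # on: their death move is always rejected, so skip proposing it
    support_count = (L > 0).sum(axis=1)
    pinned = {
        t
        for t in range(n_cands)
        if np.any((support_count == 1) & (L[:, t] > 0))
    }
    movable = [t for t in range(n_cands) if t not in pinned]
    # full toggle pass per sweep for small graphs; round-robin window for
    # large candidate sets so a sweep stays O(window * n_frags * n_cands)
    window = 8
    for sweep in range(config.burn_in + config.sweeps):
        if len(movable) <= window:
            toggle_ts = movable
        else:
            start = (sweep * window) % len(movable)
            toggle_ts = [
                movable[(start + j) % len(movable)] for j in range(window)
            ]
        state = gibbs_sweep(state, L, config, rng, logL, compat_cols, toggle_ts)
        if sweep >= config.burn_in:
            c_sum += state.c
            e_sum += state.e
            kept += 1
            if states is not None:
                states.append(state.c.copy())
    summary = PosteriorSummary(
        expression_prob=c_sum / kept,
        mean_abundance=e_sum / kept,
        n_samples=kept,
        burn_in=config.burn_in,
        n_fragments=n_frags,
    )
    if record_states:
        return summary, states
    return summary


def fragment_node_path(
    fragment: ReadPair, graph: SplicingGraph, stranded: bool = True
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Ordered node path touched by each mate (k-mers looked up in the graph)."""

    def path_of(seq: str) -> tuple[str, ...]:
        nodes: list[str] = []
        for km in iter_kmers(seq, graph.k):
            hit = graph.kmer_to_node.get(km)
            if hit is None and not stranded:
                hit = graph.kmer_to_node.get(reverse_complement(km))
            if hit and (not nodes or nodes[-1] != hit[0]):
                nodes.append(hit[0])
        return tuple(nodes)

    m2 = reverse_complement(fragment.mate2) if fragment.mate2 else ""
    return path_of(fragment.mate1), path_of(m2)


def call_transcripts(
    graph: SplicingGraph,
    candidates: Sequence[CandidateTranscript],
    fragments: Sequence[ReadPair],
    config: GibbsConfig,
    rng: np.random.Generator,
    flen_dist: FragmentLengthDist | None = None,
    stranded: bool = True,
    min_length: int = 0,
) -> tuple[list[AssembledTranscript], PosteriorSummary]:
    """Call expressed transcripts of one graph from its candidates.

    Fragments incompatible with every candidate are discarded (with a logged
    count).  A candidate is called when its posterior expression probability
    reaches ``config.call_threshold``; reported abundances are posterior
    means renormalized over the called set.
    """
    if not candidates:
        raise ValueError(f"{graph.graph_id}: no candidates to call from")
    if flen_dist is None:
        flen_dist = FragmentLengthDist(lo=graph.k)
    for frag in fragments:
        graph.compat[frag.fragment_id] = fragment_node_path(frag, graph, stranded)
    L = likelihood_matrix(fragments, candidates, flen_dist, graph.k, stranded)
    usable = L.sum(axis=1) > 0
    dropped = int((~usable).sum())
    L = L[usable]
    n_cands = len(candidates)
    if L.shape[0] == 0:
        logger.warning(
            "%s: no fragment compatible with any candidate; graph unexplainable",
            graph.graph_id,
        )
        summary = PosteriorSummary(
            expression_prob=np.zeros(n_cands),
            mean_abundance=np.zeros(n_cands),
            n_samples=0,
            burn_in=config.burn_in,
            n_fragments=0,
            n_fragments_dropped=dropped,
        )
        return [], summary
    if dropped:
        logger.info("%s: dropped %d incompatible fragments", graph.graph_id, dropped)
    if n_cands == 1:
        # degenerate conditionals: single candidate explains everything
        summary = PosteriorSummary(
            expression_prob=np.ones(1),
            mean_abundance=np.ones(1),
            n_samples=config.sweeps,
            burn_in=config.burn_in,
            n_fragments=int(L.shape[0]),
            n_fragments_dropped=dropped,
        )
    else:
        summary = run_gibbs(L, config, rng)
        summary.n_fragments_dropped = dropped
    called = [
        t
        for t in range(n_cands)
        if summary.expression_prob[t] >= config.call_threshold
        and len(candidates[t].sequence) >= min_length
    ]
    total_ab = sum(summary.mean_abundance[t] for t in called)
    out = []
    for j, t in enumerate(called, start=1):
        ab = summary.mean_abundance[t] / total_ab if total_ab > 0 else 0.0
        out.append(
            AssembledTranscript(
                transcript_id=f"{graph.graph_id}.t{j}",
                sequence=candidates[t].sequence,
                graph_id=graph.graph_id,
                abundance=float(ab),
                posterior_expression=float(summary.expression_prob[t]),
            )
        )
    return out, summary
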