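"""Read-guided construction of splicing graphs from a filtered k-mer table.

A locus is grown in four phases:

1. seed selection — the most frequent unused k-mer with base-composition
   entropy > 1.5 bits and count > 1 (low-complexity and singleton k-mers
   make unreliable anchors);
2. greedy bidirectional contig extension over k-1 overlaps, always taking
   the most frequent unused continuation;
3. paired-end rescue — when overlap extension stalls, a fragment with one
   mate anchored near the contig end and the other mate reaching beyond it
   can spell the continuation, but only from actual mate sequence (no gap
   filling with N);
4. read-guided branch extension — an alternative continuation k-mer opens
   a branch only when a read ties it to the current locus; branches run
   until they die out or rejoin previously used k-mers of the graph.

The collected locus sequence is then condensed into a splicing graph whose
nodes are unitigs (maximal unbranched k-mer chains) and whose edges are
k-1 overlaps.  Adjacency between two k-mers is only realized when the
junction-spanning (k+1)-mer occurs in at least one read, so every edge of
every graph is witnessed by a read crossing it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io import ReadPair, reverse_complement
from .kmers import KmerTable, canonical, iter_kmers, shannon_entropy

_BASES = "ACGT"


@dataclass
class Contig:
    """A spelled sequence plus the table count of each constituent k-mer.

    Coverage 0 marks k-mers spelled by paired-end rescue across a gap in the
    filtered table.
    """

    sequence: str
    kmer_coverage: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SplicingGraph:
    """Directed graph of exon-like unitig nodes joined by splice junctions.

    ``edges`` maps ``(from_node, to_node)`` to the number of read-level
    witnesses of the junction-spanning (k+1)-mer.  ``compat`` is filled by
    the transcript-calling stage with per-fragment node paths.
    """

    graph_id: str
    k: int
    nodes: dict[str, Contig] = field(default_factory=dict)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    seed_kmer: str = ""
    kmer_to_node: dict[str, tuple[str, int]] = field(default_factory=dict)
    compat: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=dict
    )

    def successors(self, node_id: str) -> list[str]:
        return sorted(v for (u, v) in self.edges if u == node_id)

    def predecessors(self, node_id: str) -> list[str]:
        return sorted(u for (u, v) in self.edges if v == node_id)

    def to_gfa(self, path: str | Path) -> None:
        """Dump as GFA 1.0 (segments = nodes, links with k-1 overlap)."""
        with open(path, "w") as fh:
            fh.write("H\tVN:Z:1.0\n")
            for nid in sorted(self.nodes):
                fh.write(f"S\t{nid}\t{self.nodes[nid].sequence}\n")
            for (u, v) in sorted(self.edges):
                fh.write(f"L\t{u}\t+\t{v}\t+\t{self.k - 1}M\n")


class ReadIndex:
    """Occurrence index of read k-mers plus junction (k+1)-mer counts.

    Mate 2 is stored reverse-complemented so both mates of a fragment lie on
    one strand.  Occurrence lists are capped (branch-support queries need a
    handful of witnesses, not all of them); the junction counter is exact.
    """

    def __init__(
        self,
        pairs: Sequence[ReadPair],
        k: int,
        stranded: bool = True,
        max_occurrences: int = 16,
    ) -> None:
        self.k = k
        self.stranded = stranded
        self.pairs = list(pairs)
        self.oriented: list[tuple[str, str]] = []
        self.occ: dict[str, list[tuple[int, int]]] = {}
        self.junctions: Counter[str] = Counter()
        occ = self.occ
        junc = self.junctions
        for pi, pair in enumerate(self.pairs):
            m1 = pair.mate1
            m2 = reverse_complement(pair.mate2) if pair.mate2 else ""
            self.oriented.append((m1, m2))
            for mate_code, seq in ((0, m1), (1, m2)):
                if not seq:
                    continue
                for km in iter_kmers(seq, k):
                    key = km if stranded else canonical(km)
                    lst = occ.get(key)
                    if lst is None:
                        occ[key] = [(pi, mate_code)]
                    elif len(lst) < max_occurrences:
                        lst.append((pi, mate_code))
                for jm in iter_kmers(seq, k + 1):
                    junc[jm if stranded else canonical(jm)] += 1

    def key(self, kmer: str) -> str:
        return kmer if self.stranded else canonical(kmer)

    def junction_support(self, kmer_plus_one: str) -> int:
        """Number of read windows spanning this (k+1)-mer junction."""
        return self.junctions.get(self.key(kmer_plus_one), 0)

    def mate_seq(self, pair_idx: int, mate_code: int) -> str:
        return self.oriented[pair_idx][mate_code]


def select_seed(
    table: KmerTable,
    used: set[str],
    min_entropy: float = 1.5,
    min_count: int = 2,
) -> str | None:
    """Most frequent unused k-mer with H > ``min_entropy`` and count > 1.

    Ties broken lexicographically; None when no k-mer qualifies.
    """
    best: str | None = None
    best_count = 0
    for kmer, count in table.counts.items():
        if count < min_count or kmer in used:
            continue
        if count < best_count or (count == best_count and best is not None and kmer > best):
            continue
        if shannon_entropy(kmer) > min_entropy:
            best, best_count = kmer, count
    return best


def _best_unused(
    candidates: Iterable[str], table: KmerTable, used: set[str]
) -> str | None:
    """Most frequent unused table k-mer among candidates; ties lexicographic."""
    best = None
    best_count = 0
    for km in candidates:
        key = table.key(km)
        if key in used:
            continue
        count = table.counts.get(key, 0)
        if count and (count > best_count or (count == best_count and km < best)):
            best, best_count = km, count
    return best


def _consume(kmer: str, table: KmerTable, used: set[str], locus: set[str]) -> None:
    key = table.key(kmer)
    used.add(key)
    locus.add(key)


def _extend_right(
    seq: str,
    cov: list[int],
    table: KmerTable,
    used: set[str],
    locus: set[str],
) -> str:
    k = table.k
    while True:
        suffix = seq[-(k - 1) :]
        nxt = _best_unused((suffix + b for b in _BASES), table, used)
        if nxt is None:
            return seq
        seq += nxt[-1]
        cov.append(table.get(nxt))
        _consume(nxt, table, used, locus)


def _extend_left(
    seq: str,
    cov: list[int],
    table: KmerTable,
    used: set[str],
    locus: set[str],
) -> str:
    k = table.k
    while True:
        prefix = seq[: k - 1]
        nxt = _best_unused((b + prefix for b in _BASES), table, used)
        if nxt is None:
            return seq
        seq = nxt[0] + seq
        cov.insert(0, table.get(nxt))
        _consume(nxt, table, used, locus)


def extend_contig(
    seed: str,
    table: KmerTable,
    used: set[str],
    locus: set[str] | None = None,
) -> Contig:
    """Greedy bidirectional extension of a seed over k-1 overlaps.

    Repeatedly appends (then prepends) the base whose continuation k-mer is
    the most frequent unused table entry; every consumed k-mer is marked
    used.  Stops in a direction when no unused overlapping k-mer exists.
    """
    if seed not in table:
        raise ValueError(f"seed {seed!r} not in k-mer table")
    if table.key(seed) in used:
        raise ValueError(f"seed {seed!r} already used")
    if locus is None:
        locus = set()
    cov = [table.get(seed)]
    _consume(seed, table, used, locus)
    seq = _extend_right(seed, cov, table, used, locus)
    seq = _extend_left(seq, cov, table, used, locus)
    return Contig(sequence=seq, kmer_coverage=cov)


def _overlap_suffix_prefix(a: str, b: str, min_overlap: int) -> int:
    """Largest o >= min_overlap with a's suffix == b's prefix (0 if none).

    Anchored on b's first ``min_overlap`` bases with str.find, then verified
    in one comparison per occurrence — far cheaper than trying every o.
    """
    max_o = min(len(a), len(b) - 1)  # b must extend beyond the overlap
    if max_o < min_overlap:
        return 0
    region = a[-max_o:]
    probe = b[:min_overlap]
    best = 0
    idx = region.find(probe)
    while idx != -1:
        o = len(region) - idx
        if o >= min_overlap and region[idx:] == b[:o]:
            best = max(best, o)
        idx = region.find(probe, idx + 1)
    return best


def _overlap_prefix_suffix(a: str, b: str, min_overlap: int) -> int:
    """Largest o >= min_overlap with a's prefix == b's suffix (0 if none)."""
    max_o = min(len(a), len(b) - 1)
    if max_o < min_overlap:
        return 0
    region = b[-max_o:]
    probe = a[:min_overlap]
    best = 0
    idx = region.find(probe)
    while idx != -1:
        o = len(region) - idx
        if o >= min_overlap and region[idx:] == a[:o]:
            best = max(best, o)
        idx = region.find(probe, idx + 1)
    return best


def _sparse_kmers(seq: str, k: int, step: int):
    """Every step-th k-length window (a mate anchors at ~76 consecutive
    windows, so a sparse scan still finds every anchored fragment)."""
    for i in range(0, len(seq) - k + 1, step):
        yield seq[i : i + k]


def _pe_candidates_right(
    seq: str,
    index: ReadIndex,
    table: KmerTable,
    used: set[str],
    window: int,
    min_overlap: int,
) -> Counter[str]:
    """Extension strings spelled by far mates of fragments anchored near the
    right end, keyed by the spelled continuation."""
    k = table.k
    tail = seq[-window:]
    found: Counter[str] = Counter()
    seen_pairs: set[int] = set()
    for km in _sparse_kmers(tail, k, 4):
        for pi, mate_code in index.occ.get(index.key(km), ()):
            if pi in seen_pairs:
                continue
            seen_pairs.add(pi)
            m = index.mate_seq(pi, mate_code)
            if km in m:
                same_strand = True
            elif not index.stranded and reverse_complement(km) in m:
                same_strand = False
            else:
                continue
            if same_strand:
                if mate_code != 0:
                    continue  # anchored mate2: fragment extends leftward
                far = index.mate_seq(pi, 1)
            else:
                if mate_code != 1:
                    continue
                far = reverse_complement(index.mate_seq(pi, 0))
            if not far:
                continue
            o = _overlap_suffix_prefix(seq, far, min_overlap)
            if o == 0:
                continue
            ext = far[o:]
            # no circularization: reject if the spelled continuation re-enters
            # already-used k-mer territory
            joint = seq[-(k - 1) :] + ext
            if any(table.key(km2) in used for km2 in iter_kmers(joint, k)):
                continue
            if "N" in ext:
                continue
            found[ext] += 1
    return found


def _pe_candidates_left(
    seq: str,
    index: ReadIndex,
    table: KmerTable,
    used: set[str],
    window: int,
    min_overlap: int,
) -> Counter[str]:
    k = table.k
    head = seq[:window]
    found: Counter[str] = Counter()
    seen_pairs: set[int] = set()
    for km in _sparse_kmers(head, k, 4):
        for pi, mate_code in index.occ.get(index.key(km), ()):
            if pi in seen_pairs:
                continue
            seen_pairs.add(pi)
            m = index.mate_seq(pi, mate_code)
            if km in m:
                same_strand = True
            elif not index.stranded and reverse_complement(km) in m:
                same_strand = False
            else:
                continue
            if same_strand:
                if mate_code != 1:
                    continue  # anchored mate1: fragment extends rightward
                far = index.mate_seq(pi, 0)
            else:
                if mate_code != 0:
                    continue
                far = reverse_complement(index.mate_seq(pi, 1))
            if not far:
                continue
            o = _overlap_prefix_suffix(seq, far, min_overlap)
            if o == 0:
                continue
            ext = far[: len(far) - o]
            joint = ext + seq[: k - 1]
            if any(table.key(km2) in used for km2 in iter_kmers(joint, k)):
                continue
            if "N" in ext:
                continue
            found[ext] += 1
    return found


def paired_end_extend(
    contig: Contig,
    index: ReadIndex,
    table: KmerTable,
    used: set[str],
    locus: set[str] | None = None,
    anchor_window: int = 300,
    min_overlap: int = 15,
) -> Contig:
    """Extend a stalled contig across table gaps using paired-end mates.

    A fragment with one mate anchored (exact k-mer match) near a contig end
    and its far mate overlapping that end by >= k-1 bases spells the
    continuation; the most supported spelling wins (ties lexicographic).
    Extension then resumes greedily from the new end.  The contig is returned
    unchanged when no anchored fragment bridges the gap.
    """
    if locus is None:
        locus = set()
    k = table.k
    seq = contig.sequence
    cov = list(contig.kmer_coverage)
    rounds = 0
    progress = True
    while progress and rounds < 8:
        rounds += 1
        progress = False
        cands = _pe_candidates_right(seq, index, table, used, anchor_window, min_overlap)
        if cands:
            top = max(cands.values())
            best = min(e for e in cands if cands[e] == top)
            joint = seq[-(k - 1) :] + best
            for km in iter_kmers(joint, k):
                cov.append(table.get(km))
                if km in table:
                    _consume(km, table, used, locus)
            seq += best
            seq = _extend_right(seq, cov, table, used, locus)
            progress = True
    rounds = 0
    progress = True
    while progress and rounds < 8:
        rounds += 1
        progress = False
        cands = _pe_candidates_left(seq, index, table, used, anchor_window, min_overlap)
        if cands:
            tie_count = max(cands.values())
            best = min(e for e in cands if cands[e] == tie_count)
            joint = best + seq[: k - 1]
            new_cov = []
            for km in iter_kmers(joint, k):
                new_cov.append(table.get(km))
                if km in table:
                    _consume(km, table, used, locus)
            cov = new_cov + cov
            seq = best + seq
            seq = _extend_left(seq, cov, table, used, locus)
            progress = True
    return Contig(sequence=seq, kmer_coverage=cov)


def _read_overlaps_locus(seq: str, locus: set[str], table: KmerTable) -> bool:
    return any(table.key(km) in locus for km in iter_kmers(seq, table.k))


def _branch_supported(
    alt: str,
    index: ReadIndex,
    table: KmerTable,
    locus: set[str],
) -> bool:
    """Read-guided gate for opening a branch at an alternative k-mer.

    Primary: some read contains the alternative k-mer and overlaps the
    current locus (shares >= 1 k-mer).  Fallback: a read containing the
    alternative k-mer whose *mate* is anchored on the locus.  Alternative
    k-mers lacking both (chimeric artifacts) never open branches.

    Like seed selection, opening also requires the alternative k-mer to be
    observed more than once: a singleton branch k-mer is a single read's
    claim, which at moderate coverage is most often a sequencing error that
    escaped the dominance filter.
    """
    if table.counts.get(table.key(alt), 0) < 2:
        return False
    occurrences = index.occ.get(index.key(alt), ())
    for pi, mate_code in occurrences:
        m = index.mate_seq(pi, mate_code)
        if _read_overlaps_locus(m, locus, table):
            return True
    for pi, mate_code in occurrences:
        other = index.mate_seq(pi, 1 - mate_code)
        if other and _read_overlaps_locus(other, locus, table):
            return True
    return False


def _alternative_kmers(seg: str, i: int, k: int) -> Iterable[tuple[str, bool]]:
    """(alternative k-mer, is_successor) pairs at position i of a segment."""
    kmer = seg[i : i + k]
    if i + k < len(seg):
        actual = seg[i + k]
        core = kmer[1:]
        for b in _BASES:
            if b != actual:
                yield core + b, True
    if i > 0:
        actual = seg[i - 1]
        core = kmer[: k - 1]
        for b in _BASES:
            if b != actual:
                yield b + core, False


def _hamming_close(a: str, b: str, budget: int) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return False
    return True


def _is_bubble(branch_seq: str, seg: str, i: int, successor: bool, k: int) -> bool:
    """A substitution bubble runs parallel to its parent segment for ~k
    bases at Hamming distance ~1 — the footprint of a sequencing error that
    escaped the dominance filter (a real skip junction, though just as
    short, parallels a whole skipped exon instead)."""
    if len(branch_seq) > 2 * k + 5:
        return False
    if successor:
        window = seg[i + 1 : i + 1 + len(branch_seq)]
    else:
        end = i + k - 1
        window = seg[max(0, end - len(branch_seq)) : end]
    return _hamming_close(branch_seq, window, 2)


def _scan_branches(
    segments: list[str],
    table: KmerTable,
    index: ReadIndex,
    used: set[str],
    locus: set[str],
    max_branches: int,
    anchor_window: int,
    min_pe_overlap: int = 15,
) -> None:
    """Open read-supported branches off every segment, recursively (branches
    of branches), bounded by ``max_branches`` openings; appends in place.

    Substitution bubbles are popped: their k-mers are absorbed (marked used
    so they neither re-open nor seed junk loci) but contribute no segment.
    """
    k = table.k
    queue = list(segments)
    openings = 0
    while queue and openings < max_branches:
        seg = queue.pop(0)
        for i in range(len(seg) - k + 1):
            if openings >= max_branches:
                break
            for alt, successor in _alternative_kmers(seg, i, k):
                key = table.key(alt)
                if key in used or key not in table.counts:
                    continue
                if not _branch_supported(alt, index, table, locus):
                    continue
                consumed: set[str] = set()
                branch = extend_contig(alt, table, used, consumed)
                if _is_bubble(branch.sequence, seg, i, successor, k):
                    continue  # popped: k-mers stay used, no segment added
                locus.update(consumed)
                branch = paired_end_extend(
                    branch, index, table, used, locus, anchor_window, min_pe_overlap
                )
                segments.append(branch.sequence)
                queue.append(branch.sequence)
                openings += 1
                if openings >= max_branches:
                    break


def _collect_locus(
    seed: str,
    table: KmerTable,
    index: ReadIndex,
    used: set[str],
    max_branches: int = 20,
    anchor_window: int = 300,
    min_pe_overlap: int = 15,
) -> tuple[list[str], set[str], Contig]:
    """Grow one locus: main contig plus read-supported branches.

    Returns (segment sequences, locus k-mer keys, main contig).
    """
    locus: set[str] = set()
    main = extend_contig(seed, table, used, locus)
    main = paired_end_extend(
        main, index, table, used, locus, anchor_window, min_pe_overlap
    )
    segments = [main.sequence]
    _scan_branches(
        segments, table, index, used, locus, max_branches, anchor_window, min_pe_overlap
    )
    return segments, locus, main


def _mean_coverage(contig: Contig) -> float:
    cov = contig.kmer_coverage
    return sum(cov) / len(cov) if cov else 0.0


def _graph_cleanup(
    contigs: list[Contig],
    edges: dict[tuple[int, int], int],
    k: int,
    max_rounds: int = 10,
) -> set[int]:
    """Indices of nodes to drop: substitution bubbles and error tips.

    A parallel bubble is a pair of nodes sharing all predecessors and all
    successors whose sequences differ by a few substitutions — the graph
    footprint of a recurrent sequencing error; the lower-coverage twin is
    dropped.  A tip is a short (<= 2k+5) node dangling off the graph on one
    side only.  Iterated to a fixpoint since trimming can expose new tips.
    """
    removed: set[int] = set()
    short = 2 * k + 5
    for _ in range(max_rounds):
        changed = False
        preds: dict[int, set[int]] = {}
        succs: dict[int, set[int]] = {}
        for (u, v) in edges:
            if u in removed or v in removed:
                continue
            succs.setdefault(u, set()).add(v)
            preds.setdefault(v, set()).add(u)
        # short dangling tips (one connected side only)
        for ci, contig in enumerate(contigs):
            if ci in removed or len(contig.sequence) > short:
                continue
            has_in = bool(preds.get(ci))
            has_out = bool(succs.get(ci))
            if has_in != has_out:
                removed.add(ci)
                changed = True
        # parallel bubbles
        groups: dict[tuple, list[int]] = {}
        for ci in range(len(contigs)):
            if ci in removed:
                continue
            p = frozenset(preds.get(ci, ()) ) - removed
            q = frozenset(succs.get(ci, ()) ) - removed
            if p and q:
                groups.setdefault((frozenset(p), frozenset(q)), []).append(ci)
        for members in groups.values():
            if len(members) < 2:
                continue
            members = sorted(
                members, key=lambda ci: -_mean_coverage(contigs[ci])
            )
            keep = [members[0]]
            for ci in members[1:]:
                twin = None
                for cj in keep:
                    a, b = contigs[ci].sequence, contigs[cj].sequence
                    if abs(len(a) - len(b)) <= 4 and _hamming_close(
                        a, b[: len(a)], 3
                    ):
                        twin = cj
                        break
                if twin is not None:
                    removed.add(ci)
                    changed = True
                else:
                    keep.append(ci)
        if not changed:
            break
    return removed


def _condense(
    segments: list[str],
    table: KmerTable,
    index: ReadIndex,
) -> list[tuple[dict[str, Contig], dict[tuple[str, str], int], dict[str, tuple[str, int]]]]:
    """Condense locus k-mers into unitig nodes and witnessed junction edges.

    Adjacency x -> y (y = x[1:] + b) is realized only when the junction
    (k+1)-mer x+b occurs in a read.  Returns one (nodes, edges, kmer map)
    triple per weakly connected component, in deterministic order.
    """
    k = table.k
    kmer_set: set[str] = set()
    for seg in segments:
        kmer_set.update(iter_kmers(seg, k))

    # adjacency: spelled consecutively within a collected segment (contig
    # internals, incl. paired-end-rescued gaps) OR read-witnessed junction
    adj: dict[str, set[str]] = {x: set() for x in kmer_set}
    radj: dict[str, set[str]] = {x: set() for x in kmer_set}
    for seg in segments:
        prev = None
        for km in iter_kmers(seg, k):
            if prev is not None:
                adj[prev].add(km)
                radj[km].add(prev)
            prev = km
    for x in kmer_set:
        core = x[1:]
        for b in _BASES:
            y = core + b
            if y in adj and index.junction_support(x + b) > 0:
                adj[x].add(y)
                radj[y].add(x)

    def succs(x: str) -> list[str]:
        return sorted(adj[x])

    def preds(x: str) -> list[str]:
        return sorted(radj[x])

    # unitig starts: k-mers that cannot be absorbed into a predecessor chain
    starts = []
    for x in kmer_set:
        p = preds(x)
        if len(p) != 1 or len(succs(p[0])) != 1:
            starts.append(x)
    starts.sort()

    chains: list[list[str]] = []
    in_chain: set[str] = set()
    for s in starts:
        if s in in_chain:
            continue
        chain = [s]
        in_chain.add(s)
        cur = s
        while True:
            nxt = succs(cur)
            if len(nxt) != 1:
                break
            y = nxt[0]
            if len(preds(y)) != 1 or y in in_chain:
                break
            chain.append(y)
            in_chain.add(y)
            cur = y
        chains.append(chain)
    # isolated cycles (no chain start) — break each at its smallest k-mer
    leftover = sorted(kmer_set - in_chain)
    for s in leftover:
        if s in in_chain:
            continue
        chain = [s]
        in_chain.add(s)
        cur = s
        while True:
            nxt = succs(cur)
            if len(nxt) != 1:
                break
            y = nxt[0]
            if y in in_chain:
                break
            chain.append(y)
            in_chain.add(y)
            cur = y
        chains.append(chain)

    chains.sort(key=lambda c: c[0])
    node_of: dict[str, int] = {}
    contigs: list[Contig] = []
    for ci, chain in enumerate(chains):
        seq = chain[0] + "".join(x[-1] for x in chain[1:])
        cov = [table.get(x) for x in chain]
        contigs.append(Contig(sequence=seq, kmer_coverage=cov))
        for x in chain:
            node_of[x] = ci
    # inter-node edges must themselves be read-witnessed: a spelled-only
    # adjacency that lands on a node boundary is dropped rather than turned
    # into an edge no read spans
    edges: dict[tuple[int, int], int] = {}
    for ci, chain in enumerate(chains):
        last = chain[-1]
        for y in succs(last):
            support = index.junction_support(last + y[-1])
            if support > 0:
                edges[(ci, node_of[y])] = support

    # graph hygiene: pop parallel substitution bubbles and trim short tips
    # left by sequencing errors that escaped the k-mer dominance filter
    removed = _graph_cleanup(contigs, edges, k)
    if removed:
        edges = {
            (u, v): sup
            for (u, v), sup in edges.items()
            if u not in removed and v not in removed
        }
        for x in [x for x, ci in node_of.items() if ci in removed]:
            del node_of[x]

    # weakly connected components
    parent = list(range(len(chains)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for (u, v) in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv

    comp_members: dict[int, list[int]] = {}
    for ci in range(len(chains)):
        if ci in removed:
            continue  # popped bubbles/tips: k-mers stay consumed, no node
        comp_members.setdefault(find(ci), []).append(ci)

    results = []
    for root in sorted(comp_members, key=lambda r: chains[comp_members[r][0]][0]):
        members = comp_members[root]
        rename = {ci: f"n{j:03d}" for j, ci in enumerate(members)}
        nodes = {rename[ci]: contigs[ci] for ci in members}
        comp_edges = {
            (rename[u], rename[v]): sup
            for (u, v), sup in edges.items()
            if u in rename and v in rename
        }
        kmap = {
            x: (rename[node_of[x]], pos)
            for ci in members
            for pos, x in enumerate(chains[ci])
            if node_of[x] == ci
        }
        results.append((nodes, comp_edges, kmap))
    return results


def branch_extend(
    main: Contig,
    table: KmerTable,
    index: ReadIndex,
    used: set[str],
    max_branches: int = 20,
    anchor_window: int = 300,
) -> SplicingGraph:
    """Open read-supported branches off a main contig and condense the locus.

    Returns the splicing graph containing the main contig's seed region.
    (When unwitnessed adjacencies split the locus, the component holding the
    main contig's first k-mer is returned; :func:`build_all_graphs` keeps all
    components.)
    """
    k = table.k
    seed = main.sequence[:k]
    # the main contig's k-mers were consumed when it was built; rebuild the
    # locus bookkeeping from its sequence
    locus = {table.key(km) for km in iter_kmers(main.sequence, k)}
    used.update(locus)
    segments = [main.sequence]
    _scan_branches(segments, table, index, used, locus, max_branches, anchor_window)
    components = _condense(segments, table, index)
    for nodes, edges, kmap in components:
        if seed in kmap:
            return SplicingGraph(
                graph_id="g00000",
                k=k,
                nodes=nodes,
                edges=edges,
                seed_kmer=min(kmap),
                kmer_to_node=kmap,
            )
    nodes, edges, kmap = components[0]
    return SplicingGraph(
        graph_id="g00000", k=k, nodes=nodes, edges=edges,
        seed_kmer=min(kmap), kmer_to_node=kmap,
    )


def build_all_graphs(
    table: KmerTable,
    index: ReadIndex,
    min_entropy: float = 1.5,
    min_seed_count: int = 2,
    max_branches: int = 20,
    anchor_window: int = 300,
    min_pe_overlap: int = 15,
) -> list[SplicingGraph]:
    """Loop seed -> extend -> branch-extend until no seed qualifies.

    Each iteration consumes one locus (nominally one gene); loci are
    disjoint in k-mer usage.  Graphs are returned sorted by their smallest
    k-mer (a deterministic processing order) and numbered ``g00000``...
    """
    used: set[str] = set()
    # qualifying seeds, most frequent first, lexicographic tie-break
    seed_order = sorted(
        (km for km, c in table.counts.items() if c >= min_seed_count),
        key=lambda km: (-table.counts[km], km),
    )
    raw: list[tuple[str, dict, dict, dict]] = []
    for seed in seed_order:
        if table.key(seed) in used:
            continue
        if shannon_entropy(seed) <= min_entropy:
            continue
        segments, locus, _main = _collect_locus(
            seed, table, index, used, max_branches, anchor_window, min_pe_overlap
        )
        for nodes, edges, kmap in _condense(segments, table, index):
            raw.append((min(kmap), nodes, edges, kmap))
    raw.sort(key=lambda item: item[0])
    graphs = []
    for gi, (first_kmer, nodes, edges, kmap) in enumerate(raw):
        graphs.append(
            SplicingGraph(
                graph_id=f"g{gi:05d}",
                k=table.k,
                nodes=nodes,
                edges=edges,
                seed_kmer=first_kmer,
                kmer_to_node=kmap,
            )
        )
    return graphs


def verify_edge_support(
    graph: SplicingGraph, pairs: Sequence[ReadPair], stranded: bool = True
) -> list[tuple[str, str]]:
    """Re-scan reads and return edges NOT spanned by any read (should be []).

    An edge u->v is spanned when the (k+1)-mer formed by u's last k-mer plus
    v's following base occurs in some mate (mate 2 taken on the transcript
    strand when stranded; either strand otherwise).
    """
    k = graph.k
    junctions = {}
    for (u, v) in graph.edges:
        jm = graph.nodes[u].sequence[-k:] + graph.nodes[v].sequence[k - 1]
        junctions[(u, v)] = jm
    witnessed: set[str] = set()
    targets = set(junctions.values())
    if not stranded:
        targets |= {reverse_complement(j) for j in targets}
    for pair in pairs:
        for seq in (pair.mate1, reverse_complement(pair.mate2) if pair.mate2 else ""):
            if not seq:
                continue
            for jm in iter_kmers(seq, k + 1):
                if jm in targets:
                    witnessed.add(jm if stranded else canonical(jm))
    out = []
    for (u, v), jm in junctions.items():
        key = jm if stranded else canonical(jm)
        if key not in witnessed:
            out.append((u, v))
    return sorted(out)
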