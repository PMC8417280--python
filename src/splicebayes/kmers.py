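"""k-mer counting, error filtering and sequence-complexity scoring.

Reads are decomposed into length-k windows held in a hash table.  In
stranded mode mate 2 is reverse-complemented first, so both mates count
on the transcript strand; in unstranded mode counts are accumulated on
the canonical form (lexicographic minimum of a k-mer and its reverse
complement).  Windows containing N are skipped.

Erroneous k-mers are removed by a dominance rule: a singleton k-mer is
discarded when a single-substitution neighbour out-counts it by at least
``min_dominance_ratio`` (default 20x) — the signature of a sequencing
error hanging off a well-covered k-mer.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .io import ReadPair, reverse_complement

_BASES = "ACGT"


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int) -> Iterator[str]:
    """All length-k windows of ``seq`` that contain no N.

    N positions are located once so runs between them are scanned without
    per-window membership tests.
    """
    n = len(seq)
    if n < k:
        return
    if "N" not in seq:
        for i in range(n - k + 1):
            yield seq[i : i + k]
        return
    start = 0
    while start <= n - k:
        nxt = seq.find("N", start)
        end = n if nxt == -1 else nxt
        for i in range(start, end - k + 1):
            yield seq[i : i + k]
        if nxt == -1:
            return
        start = nxt + 1


@dataclass
class KmerTable:
    """Hash table of k-mer counts with strand bookkeeping."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    stranded: bool = True

    def key(self, kmer: str) -> str:
        return kmer if self.stranded else canonical(kmer)

    def get(self, kmer: str) -> int:
        """Count for a k-mer as observed (canonicalized if unstranded)."""
        return self.counts.get(self.key(kmer), 0)

    def __contains__(self, kmer: str) -> bool:
        return self.key(kmer) in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def total(self) -> int:
        return sum(self.counts.values())

    def dump_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def load_tsv(cls, path: str | Path, k: int, stranded: bool = True) -> "KmerTable":
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                kmer, cnt = line.split("\t")
                counts[kmer] = int(cnt)
        return cls(k=k, counts=counts, stranded=stranded)


def build_kmer_table(
    reads: Iterable[ReadPair], k: int, stranded: bool = True
) -> KmerTable:
    """Count every usable k-mer window of every mate.

    In stranded mode mate 2 is reverse-complemented before counting so that
    both mates contribute k-mers on the transcript strand.  Raises a
    configuration error if k exceeds the shortest mate seen.
    """
    if k < 1:
        raise ValueError(f"k must be positive, got {k}")
    counts: Counter[str] = Counter()
    shortest = None
    for pair in reads:
        mates = [pair.mate1]
        if pair.mate2:
            mates.append(reverse_complement(pair.mate2) if stranded else pair.mate2)
        for mate in mates:
            if shortest is None or len(mate) < shortest:
                shortest = len(mate)
            if stranded:
                counts.update(iter_kmers(mate, k))
            else:
                for km in iter_kmers(mate, k):
                    counts[canonical(km)] += 1
    if shortest is not None and k > shortest:
        raise ValueError(
            f"k={k} exceeds shortest read length {shortest}"
        )
    return KmerTable(k=k, counts=dict(counts), stranded=stranded)


def _substitution_neighbors(kmer: str) -> Iterator[str]:
    for i, base in enumerate(kmer):
        prefix, suffix = kmer[:i], kmer[i + 1 :]
        for b in _BASES:
            if b != base:
                yield prefix + b + suffix


def filter_errors(
    table: KmerTable,
    min_dominance_ratio: float = 20.0,
    min_count: int = 1,
) -> KmerTable:
    """Drop dominated singleton k-mers (and anything below ``min_count``).

    A k-mer with count 1 is removed when some single-substitution neighbour
    has count >= ``min_dominance_ratio`` times its own.  Returns a new table;
    the input is unchanged.  Idempotent: dominators have count > 1 and are
    never removed, so a second pass removes nothing.
    """
    counts = table.counts
    kept: dict[str, int] = {}
    for kmer, cnt in counts.items():
        if cnt < min_count:
            continue
        if cnt == 1:
            threshold = min_dominance_ratio * cnt
            dominated = False
            for nb in _substitution_neighbors(kmer):
                if counts.get(table.key(nb), 0) >= threshold:
                    dominated = True
                    break
            if dominated:
                continue
        kept[kmer] = cnt
    return KmerTable(k=table.k, counts=kept, stranded=table.stranded)


def shannon_entropy(kmer: str) -> float:
    """Base-composition Shannon entropy in bits, in [0, 2] for DNA.

    H = -sum_b p_b log2 p_b over the four base frequencies within the k-mer.
    With log base 2 the maximum (uniform composition) is exactly 2 bits, so
    the seed-selection threshold of 1.5 sits meaningfully below it.
    """
    if not kmer:
        raise ValueError("entropy of empty k-mer is undefined")
    n = len(kmer)
    h = 0.0
    for base in _BASES:
        c = kmer.count(base)
        if c:
            p = c / n
            h -= p * math.log2(p)
    return h
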