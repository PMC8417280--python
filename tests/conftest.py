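"""Shared fixtures: deterministic toy transcripts and read tilings.

Reads are tiled deterministically (no RNG) so that every k-length window
and every junction of a toy transcript is covered — the precondition for
exact graph-recovery oracles.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

# deterministic property tests: examples derive from the test body, not a
# random seed, so runs are reproducible anywhere
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from splicebayes.io import ReadPair, reverse_complement
from splicebayes.simulate import random_dna

K = 25
READ_LEN = 100
FRAG_LEN = 250


def tile_pairs(
    seqs,
    frag_len: int = FRAG_LEN,
    read_len: int = READ_LEN,
    step: int = 25,
    prefix: str = "frag",
) -> list[ReadPair]:
    """Error-free paired-end fragments tiling each sequence at every `step`.

    With step <= read_len - K + 1 every window of every sequence occurs in
    some mate, so graph construction has full junction coverage.
    """
    if isinstance(seqs, str):
        seqs = [seqs]
    pairs = []
    n = 0
    for seq in seqs:
        fl = min(frag_len, len(seq))
        starts = list(range(0, len(seq) - fl + 1, step))
        if starts and starts[-1] != len(seq) - fl:
            starts.append(len(seq) - fl)
        for s in starts:
            frag = seq[s : s + fl]
            rl = min(read_len, fl)
            pairs.append(
                ReadPair(
                    f"{prefix}{n:05d}",
                    frag[:rl],
                    reverse_complement(frag[-rl:]),
                )
            )
            n += 1
    return pairs


@pytest.fixture(scope="session")
def rng0():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def cassette_toy():
    """Skipped-exon gene: isoform 1 = L+C+R, isoform 2 = L+R."""
    rng = np.random.default_rng(42)
    left = random_dna(600, rng)
    cassette = random_dna(400, rng)
    right = random_dna(600, rng)
    iso1 = left + cassette + right
    iso2 = left + right
    return {
        "left": left,
        "cassette": cassette,
        "right": right,
        "isoforms": [iso1, iso2],
    }


@pytest.fixture(scope="session")
def cassette_reads(cassette_toy):
    return tile_pairs(cassette_toy["isoforms"], step=20)
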