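"""Splicing-graph construction: seeding, extension, rescue, branching."""

import numpy as np
import pytest

from splicebayes.candidates import enumerate_candidates
from splicebayes.graph import (
    Contig,
    ReadIndex,
    build_all_graphs,
    extend_contig,
    paired_end_extend,
    select_seed,
    verify_edge_support,
)
from splicebayes.io import ReadPair
from splicebayes.kmers import KmerTable, build_kmer_table, filter_errors, iter_kmers
from splicebayes.simulate import random_dna

from conftest import K, tile_pairs


def _prep(pairs, k=K):
    table = filter_errors(build_kmer_table(pairs, k))
    index = ReadIndex(pairs, k)
    return table, index


class TestSelectSeed:
    def test_low_entropy_highest_count_skipped(self):
        table = KmerTable(
            k=8, counts={"AAAAAAAA": 500, "ACGTACGT": 40, "ACGTACGA": 2}
        )
        assert select_seed(table, set()) == "ACGTACGT"

    def test_all_singletons_yield_none(self):
        table = KmerTable(k=8, counts={"ACGTACGT": 1, "CGTACGTA": 1})
        assert select_seed(table, set()) is None

    def test_tie_broken_lexicographically(self):
        table = KmerTable(k=8, counts={"CGTACGTA": 40, "ACGTACGT": 40})
        assert select_seed(table, set()) == "ACGTACGT"

    def test_used_seeds_skipped(self):
        table = KmerTable(k=8, counts={"ACGTACGT": 40, "CGTACGTA": 30})
        assert select_seed(table, {"ACGTACGT"}) == "CGTACGTA"


class TestExtendContig:
    def test_unique_path_recovers_full_sequence(self):
        rng = np.random.default_rng(5)
        seq = random_dna(800, rng)
        table, _ = _prep(tile_pairs(seq, step=20))
        seed = seq[400 : 400 + K]
        contig = extend_contig(seed, table, set())
        assert contig.sequence == seq
        assert len(contig.kmer_coverage) == len(seq) - K + 1

    def test_isolated_seed_returns_itself(self):
        table = KmerTable(k=4, counts={"ACGT": 5})
        contig = extend_contig("ACGT", table, set())
        assert contig.sequence == "ACGT"

    def test_greedy_follows_heavier_fork(self):
        # fork: after ACGT both CGTA (30) and CGTC (5) continue; greedy
        # takes the 30-branch
        table = KmerTable(k=4, counts={"ACGT": 10, "CGTA": 30, "CGTC": 5})
        contig = extend_contig("ACGT", table, set())
        assert contig.sequence == "ACGTA"

    def test_consumed_kmers_marked_used(self):
        rng = np.random.default_rng(6)
        seq = random_dna(600, rng)
        table, _ = _prep(tile_pairs(seq, step=20))
        used = set()
        extend_contig(seq[:K], table, used)
        assert used == set(iter_kmers(seq, K))


class TestPairedEndExtend:
    def test_bridges_coverage_dip(self):
        rng = np.random.default_rng(7)
        seq = random_dna(700, rng)
        pairs = tile_pairs(seq, step=10)
        table, index = _prep(pairs)
        # simulate a filtered dip: drop three consecutive k-mers mid-sequence
        for pos in (300, 301, 302):
            del table.counts[seq[pos : pos + K]]
        used = set()
        contig = extend_contig(seq[50 : 50 + K], table, used)
        assert len(contig.sequence) < len(seq)  # stalled at the dip
        rescued = paired_end_extend(contig, index, table, used)
        assert rescued.sequence == seq

    def test_no_anchored_fragments_unchanged(self):
        rng = np.random.default_rng(8)
        seq = random_dna(300, rng)
        other = random_dna(300, rng)
        pairs = tile_pairs(other, step=20)  # reads from elsewhere only
        table = filter_errors(build_kmer_table(pairs + tile_pairs(seq, step=20), K))
        index = ReadIndex(pairs, K)
        used = set()
        contig = extend_contig(seq[:K], table, used)
        out = paired_end_extend(contig, index, table, used)
        assert out.sequence == contig.sequence

    def test_far_mate_into_used_region_rejected(self):
        rng = np.random.default_rng(9)
        part_a = random_dna(400, rng)
        part_b = random_dna(400, rng)
        seq = part_a + part_b
        pairs = tile_pairs(seq, step=10)
        table, index = _prep(pairs)
        # part B already consumed by another locus
        used = set(iter_kmers(seq, K)) - set(iter_kmers(part_a, K))
        contig = Contig(sequence=part_a, kmer_coverage=[])
        out = paired_end_extend(contig, index, table, used)
        assert out.sequence == part_a


class TestBranchExtendAndBuildAll:
    def test_cassette_toy_graph_spells_both_isoforms(
        self, cassette_toy, cassette_reads
    ):
        table, index = _prep(cassette_reads)
        graphs = build_all_graphs(table, index)
        assert len(graphs) == 1
        graph = graphs[0]
        # unitig convention: junction-overlap node carries the skip junction
        assert len(graph.nodes) == 4
        assert len(graph.edges) == 4
        cands = enumerate_candidates(graph, 100)
        assert {c.sequence for c in cands} == set(cassette_toy["isoforms"])

    def test_chimeric_kmer_opens_no_branch(self):
        rng = np.random.default_rng(10)
        seq = random_dna(600, rng)
        pairs = tile_pairs(seq, step=10)
        # a chimeric artifact: alternative continuation k-mer embedded in a
        # read that shares nothing else with the locus (count 2 so the
        # singleton-dominance filter keeps it)
        i = 200
        alt_base = next(b for b in "ACGT" if b != seq[i + K])
        chimera = seq[i + 1 : i + K] + alt_base + random_dna(75, rng)
        far = random_dna(100, rng)
        pairs = pairs + [
            ReadPair("chimA", chimera, far),
            ReadPair("chimB", chimera, far),
        ]
        table, index = _prep(pairs)
        alt_kmer = chimera[:K]
        assert alt_kmer in table  # artifact survives filtering
        graphs = build_all_graphs(table, index)
        locus = next(g for g in graphs if seq[:K] in g.kmer_to_node)
        assert len(locus.nodes) == 1
        assert len(locus.edges) == 0
        assert alt_kmer not in locus.kmer_to_node

    def test_single_transcript_single_node_no_edges(self):
        rng = np.random.default_rng(11)
        seq = random_dna(500, rng)
        table, index = _prep(tile_pairs(seq, step=20))
        graphs = build_all_graphs(table, index)
        assert len(graphs) == 1
        assert len(graphs[0].nodes) == 1
        assert graphs[0].edges == {}
        node = next(iter(graphs[0].nodes.values()))
        assert node.sequence == seq

    def test_two_dissimilar_genes_two_graphs(self):
        rng = np.random.default_rng(12)
        gene_a = random_dna(500, rng)
        gene_b = random_dna(500, rng)
        table, index = _prep(tile_pairs([gene_a, gene_b], step=20))
        graphs = build_all_graphs(table, index)
        assert len(graphs) == 2
        spelled = {next(iter(g.nodes.values())).sequence for g in graphs}
        assert spelled == {gene_a, gene_b}

    def test_empty_table_empty_list(self):
        table = KmerTable(k=K, counts={})
        index = ReadIndex([], K)
        assert build_all_graphs(table, index) == []

    def test_adding_isoform_preserves_existing_spelling(self, cassette_toy):
        iso1, iso2 = cassette_toy["isoforms"]
        reads1 = tile_pairs(iso1, step=20)
        table1, index1 = _prep(reads1)
        (g1,) = build_all_graphs(table1, index1)
        assert next(iter(g1.nodes.values())).sequence == iso1
        both = tile_pairs([iso1, iso2], step=20)
        table2, index2 = _prep(both)
        (g2,) = build_all_graphs(table2, index2)
        spelled = {c.sequence for c in enumerate_candidates(g2, 100)}
        assert iso1 in spelled  # nothing lost by adding the new isoform
        assert iso2 in spelled

    def test_edge_support_witnessed_by_reads(self, cassette_reads):
        table, index = _prep(cassette_reads)
        (graph,) = build_all_graphs(table, index)
        assert verify_edge_support(graph, cassette_reads) == []
        assert all(sup >= 1 for sup in graph.edges.values())

    def test_graph_kmer_disjointness(self, cassette_toy):
        rng = np.random.default_rng(13)
        other = random_dna(700, rng)
        pairs = tile_pairs(cassette_toy["isoforms"] + [other], step=20)
        table, index = _prep(pairs)
        graphs = build_all_graphs(table, index)
        seen = set()
        for g in graphs:
            assert not (seen & g.kmer_to_node.keys())
            seen |= g.kmer_to_node.keys()
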