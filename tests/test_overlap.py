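"""Overlap-graph construction against brute-force oracles.

The independent oracle throughout is the dense 4^k composition-vector dot
product (feasible for k <= 6), plus hand-enumeration on tiny sequences.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clior.io import Read
from clior.overlap import (
    build_graph,
    build_index,
    edge_weights_for_read,
    extract_kmers,
    revcomp,
)
from conftest import random_reads


def dense_dot(seq_a: str, seq_b: str, k: int, canonical: bool) -> int:
    """Oracle: explicit 4^k count vectors and their dot product."""
    alphabet = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    index = {kmer: t for t, kmer in enumerate(alphabet)}

    def vector(seq: str) -> np.ndarray:
        v = np.zeros(len(alphabet), dtype=np.int64)
        for s in range(len(seq) - k + 1):
            w = seq[s : s + k]
            if "N" in w:
                continue
            if canonical:
                w = min(w, revcomp(w))
            v[index[w]] += 1
        return v

    return int(vector(seq_a) @ vector(seq_b))


class TestExtractKmers:
    def test_plain_windows(self):
        assert extract_kmers(Read("r", "ACGTA"), 3, canonical=False) == {
            "ACG": 1, "CGT": 1, "GTA": 1,
        }

    def test_canonical_collapses_strands(self):
        # windows ACG, CGT, GTA; revcomps CGT, ACG, TAC; minima ACG, ACG, GTA
        assert extract_kmers(Read("r", "ACGTA"), 3, canonical=True) == {"ACG": 2, "GTA": 1}

    def test_n_windows_skipped(self):
        assert extract_kmers(Read("r", "ACNGT"), 3) == {}

    def test_k_longer_than_read_is_empty(self):
        assert extract_kmers(Read("r", "ACGT"), 10) == {}

    def test_read_and_its_revcomp_share_all_canonical_kmers(self):
        seq = "ACGGTTACCAGTTGA"
        fwd = extract_kmers(Read("f", seq), 5, canonical=True)
        rev = extract_kmers(Read("r", revcomp(seq)), 5, canonical=True)
        assert fwd == rev


class TestIndexAndWeights:
    def test_index_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        reads = random_reads(rng, 20, 40)
        k = 5
        index = build_index(reads, k, canonical=True)
        for kmer, postings in index.postings.items():
            for i, mult in postings:
                assert extract_kmers(reads[i], k)[kmer] == mult
        # completeness: every read k-mer appears in the postings
        for i, read in enumerate(reads):
            for kmer, mult in extract_kmers(read, k).items():
                assert (i, mult) in index.postings[kmer]

    def test_identical_reads_double_postings(self):
        reads = [Read("a", "ACGTACGTAA"), Read("b", "ACGTACGTAA")]
        index = build_index(reads, 4)
        for postings in index.postings.values():
            assert [p[0] for p in postings] == [0, 1]
            assert postings[0][1] == postings[1][1]

    @pytest.mark.parametrize("k", [4, 6])
    @pytest.mark.parametrize("canonical", [True, False])
    def test_weights_equal_dense_dot_product(self, k, canonical):
        rng = np.random.default_rng(17)
        reads = random_reads(rng, 30, 50)
        index = build_index(reads, k, canonical)
        for i in range(len(reads)):
            row = edge_weights_for_read(i, index, reads)
            for j in range(len(reads)):
                if j == i:
                    continue
                expected = dense_dot(reads[i].sequence, reads[j].sequence, k, canonical)
                assert row.get(j, 0) == expected

    def test_weight_symmetry(self):
        rng = np.random.default_rng(23)
        reads = random_reads(rng, 15, 40)
        index = build_index(reads, 4)
        rows = [edge_weights_for_read(i, index, reads) for i in range(len(reads))]
        for i in range(len(reads)):
            for j, w in rows[i].items():
                assert rows[j][i] == w

    def test_out_of_range_read_index(self):
        reads = [Read("a", "ACGTACGT")]
        index = build_index(reads, 4)
        with pytest.raises(IndexError):
            edge_weights_for_read(5, index, reads)

    def test_disjoint_reads_share_nothing(self):
        reads = [Read("a", "AAAAAAAA"), Read("b", "CCCCCCCC")]
        index = build_index(reads, 4)
        assert edge_weights_for_read(0, index, reads) == {}


class TestBuildGraph:
    def test_identical_error_free_pair(self):
        # 80 bp read with all 51 within-read 30-mers distinct: W = 51
        rng = np.random.default_rng(101)
        seq = random_reads(rng, 1, 80)[0].sequence
        assert len(set(extract_kmers(Read("x", seq), 30))) == 51
        reads = [Read("a", seq), Read("b", seq)]
        g5 = build_graph(reads, k=30, m=5)
        assert g5.weight(0, 1) == 51
        assert build_graph(reads, k=30, m=52).n_edges == 0

    def test_edge_threshold_is_inclusive(self):
        reads = [Read("a", "ACGTACGTAA"), Read("b", "ACGTACGTAA")]
        w = dense_dot(reads[0].sequence, reads[1].sequence, 4, True)
        assert build_graph(reads, k=4, m=w).has_edge(0, 1)
        assert not build_graph(reads, k=4, m=w + 1).has_edge(0, 1)

    def test_monotone_in_m(self, small_community):
        reads = small_community[0][:300]
        lo = build_graph(reads, k=30, m=5)
        hi = build_graph(reads, k=30, m=45)
        assert set(hi.weights) <= set(lo.weights)
        for edge, w in hi.weights.items():
            assert lo.weights[edge] == w

    @pytest.mark.parametrize("canonical", [True, False])
    def test_fast_path_matches_posting_list_route(self, canonical):
        """Packed-integer route vs the inverted-index accumulation."""
        rng = np.random.default_rng(31)
        reads = random_reads(rng, 25, 45) + [Read("withN", "ACGTNACGTTGCA" * 3)]
        k, m = 5, 1
        graph = build_graph(reads, k=k, m=m, canonical=canonical)
        index = build_index(reads, k, canonical)
        for i in range(len(reads)):
            row = edge_weights_for_read(i, index, reads)
            for j, w in row.items():
                assert graph.weight(i, j) == (w if w >= m else 0)
            for j in range(len(reads)):
                if j != i and j not in row:
                    assert not graph.has_edge(i, j)

    def test_overlap_guarantee(self):
        """Reads overlapping >= m+k-1 bases (distinct shared windows) get an edge."""
        rng = np.random.default_rng(77)
        genome = random_reads(rng, 1, 300)[0].sequence
        k, m = 30, 5
        a, b = genome[0:80], genome[46:126]  # overlap 34 = m + k - 1
        reads = [Read("a", a), Read("b", b)]
        graph = build_graph(reads, k=k, m=m)
        assert graph.weight(0, 1) >= m

    def test_short_reads_are_isolated(self):
        reads = [Read("tiny", "ACGT"), Read("long", "ACGTACGTACGTACGTACGTACGTACGTACGTACGT")]
        g = build_graph(reads, k=30, m=1)
        assert g.n_edges == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_fast_path_property(self, seed):
        """For arbitrary random read sets the two routes give one edge set."""
        rng = np.random.default_rng(seed)
        reads = random_reads(rng, 12, 30)
        k, m = 4, 2
        graph = build_graph(reads, k=k, m=m)
        index = build_index(reads, k, True)
        expected = {}
        for i in range(len(reads)):
            for j, w in edge_weights_for_read(i, index, reads).items():
                if j > i and w >= m:
                    expected[(i, j)] = w
        assert graph.weights == expected
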