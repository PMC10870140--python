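"""Tree construction, majority branch, ancestral/core haplotypes, pruning."""

import numpy as np
import pytest

from hstkit import (
    ancestral_haplotype,
    build_bhst,
    build_uhst,
    core_haplotype,
    majority_branch,
    merge_ancestral,
    prune_anonymize,
)
from hstkit.hst import majority_divergence_markers

from conftest import F1_ROWS, F1_START, make_matrix, random_matrix


def node_sets(hst, ids):
    return [sorted(hst.nodes[i].indexes.tolist()) for i in ids]


class TestUnidirectional:
    def test_f1_right_majority_chain_and_singleton_siblings(self, f1_matrix):
        hst = build_uhst(f1_matrix, F1_START, "right")
        chain = majority_branch(hst)
        assert node_sets(hst, chain) == [
            [0, 1, 2, 3, 4, 5], [0, 1, 2, 3, 4], [0, 1, 2, 3], [0, 1, 2], [0, 2],
        ]
        siblings = [
            sorted(hst.nodes[c].indexes.tolist())
            for nid in chain
            for c in hst.nodes[nid].children[1:]
        ]
        assert siblings == [[5], [4], [3], [1]]
        terminal = hst.nodes[chain[-1]]
        assert terminal.haplotype == [(3, 1), (4, 0), (5, 1), (6, 1)]

    def test_identical_rows_give_single_chain_node(self):
        m = make_matrix(np.tile([0, 1, 1, 0, 1], (4, 1)))
        hst = build_uhst(m, 2, "right")
        root = hst.root
        assert root.haplotype == []
        assert len(root.children) == 1
        chain = hst.nodes[root.children[0]]
        assert chain.n == 4 and chain.is_leaf
        assert chain.haplotype == [(2, 1), (3, 0), (4, 1)]

    def test_single_row_matrix_gives_root_plus_leaf(self):
        m = make_matrix(np.array([[0, 1, 0]]), ploidy=1)
        hst = build_uhst(m, 1, "right")
        assert len(hst.nodes) == 2
        leaf = hst.nodes[hst.root.children[0]]
        assert leaf.n == 1 and leaf.is_leaf

    def test_empty_matrix_and_bad_start_rejected(self, f1_matrix):
        with pytest.raises(ValueError, match="out of range"):
            build_uhst(f1_matrix, 7, "right")
        with pytest.raises(ValueError, match="out of range"):
            build_uhst(f1_matrix, -1, "left")

    def test_min_size_stops_branching(self, f1_matrix):
        hst = build_uhst(f1_matrix, F1_START, "right", min_size=3)
        # nodes below min_size are created but never expanded
        for node in hst.nodes.values():
            if node.n < 3:
                assert node.is_leaf


class TestBidirectional:
    def test_f1_root_splits_three_ways_on_allele_pairs(self, f1_matrix):
        hst = build_bhst(f1_matrix, F1_START)
        kids = node_sets(hst, hst.root.children)
        assert kids[0] == [0, 1, 2, 4]
        assert sorted(map(tuple, kids[1:])) == [(3,), (5,)]
        maj = hst.nodes[hst.root.children[0]]
        grandkids = node_sets(hst, maj.children)
        assert grandkids[0] == [0, 1]
        assert sorted(map(tuple, grandkids[1:])) == [(2,), (4,)]

    def test_every_split_has_two_to_four_children(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = random_matrix(rng, 20, 40)
            hst = build_bhst(m, 20)
            for node in hst.nodes.values():
                if node.id == hst.root_id:
                    continue
                assert len(node.children) in (0, 2, 3, 4)

    def test_identical_rows_single_chain_spanning_all_markers(self):
        m = make_matrix(np.tile([0, 1, 1, 0, 1], (4, 1)))
        hst = build_bhst(m, 2)
        chain = hst.nodes[hst.root.children[0]]
        assert chain.is_leaf and chain.n == 4
        assert [mk for mk, _ in chain.haplotype] == [0, 1, 2, 3, 4]


class TestAncestralAndCore:
    def test_f1_ancestral_haplotypes_and_merge(self, f1_matrix):
        right = ancestral_haplotype(build_uhst(f1_matrix, F1_START, "right"))
        left = ancestral_haplotype(build_uhst(f1_matrix, F1_START, "left"))
        assert right.marker_indices.tolist() == [3, 4, 5, 6]
        assert right.alleles.tolist() == [1, 0, 1, 1]
        assert left.marker_indices.tolist() == [0, 1, 2, 3]
        assert left.alleles.tolist() == [0, 1, 0, 1]
        merged = merge_ancestral(left, right, F1_START)
        assert merged.alleles.tolist() == F1_ROWS[0].tolist()

    def test_f1_bhst_ancestral_includes_uniform_right_extension(self, f1_matrix):
        hap = ancestral_haplotype(build_bhst(f1_matrix, F1_START))
        assert hap.marker_indices.tolist() == [0, 1, 2, 3, 4, 5]
        assert hap.alleles.tolist() == [0, 1, 0, 1, 0, 1]

    def test_identical_rows_ancestral_is_common_row(self):
        row = [0, 1, 1, 0, 1]
        m = make_matrix(np.tile(row, (4, 1)))
        left = ancestral_haplotype(build_uhst(m, 2, "left"))
        right = ancestral_haplotype(build_uhst(m, 2, "right"))
        assert merge_ancestral(left, right, 2).alleles.tolist() == row

    def test_ancestral_requires_two_rows(self):
        m = make_matrix(np.array([[0, 1, 0]]), ploidy=1)
        with pytest.raises(ValueError, match="at least 2"):
            ancestral_haplotype(build_uhst(m, 1, "right"))

    def test_merge_rejects_conflicting_overlap(self, f1_matrix):
        right = ancestral_haplotype(build_uhst(f1_matrix, F1_START, "right"))
        left = ancestral_haplotype(build_uhst(f1_matrix, F1_START, "left"))
        bad = left
        bad.alleles = bad.alleles.copy()
        bad.alleles[-1] ^= 1  # flip the start-marker allele
        with pytest.raises(ValueError, match="conflicting allele"):
            merge_ancestral(bad, right, F1_START)

    def test_core_empty_when_start_column_not_uniform(self, f1_matrix):
        assert len(core_haplotype(f1_matrix, F1_START)) == 0

    def test_core_is_maximal_uniform_run_through_start(self):
        m = make_matrix(F1_ROWS[[0, 1, 2, 4]], ploidy=1)
        core = core_haplotype(m, F1_START)
        assert core.marker_indices.tolist() == [1, 2, 3]
        assert core.alleles.tolist() == [1, 0, 1]

    def test_core_of_identical_rows_is_whole_row(self):
        m = make_matrix(np.tile([0, 1, 1, 0, 1], (3, 1)), ploidy=1)
        assert core_haplotype(m, 2).alleles.tolist() == [0, 1, 1, 0, 1]


class TestPruneAnonymize:
    def test_prune_drops_singleton_leaves_keeps_majority_chain(self, f1_matrix):
        hst = build_uhst(f1_matrix, F1_START, "right")
        pruned = prune_anonymize(hst, min_size=2)
        sizes = sorted(n.n for n in pruned.nodes.values())
        assert sizes == [2, 3, 4, 5, 6]  # singleton siblings all gone
        assert len(majority_branch(pruned)) == 5

    def test_min_size_one_is_identity(self, f1_matrix):
        hst = build_uhst(f1_matrix, F1_START, "right")
        pruned = prune_anonymize(hst, min_size=1)
        assert set(pruned.nodes) == set(hst.nodes)

    def test_anonymize_strips_indexes_keeps_counts(self, f1_matrix):
        hst = build_uhst(f1_matrix, F1_START, "right")
        anon = prune_anonymize(hst, min_size=1, anonymize=True)
        assert anon.samples is None and anon.anonymized
        for nid, node in anon.nodes.items():
            assert node.indexes is None
            assert node.n == hst.nodes[nid].n

    def test_min_size_above_cohort_rejected(self, f1_matrix):
        hst = build_uhst(f1_matrix, F1_START, "right")
        with pytest.raises(ValueError, match="exceeds"):
            prune_anonymize(hst, min_size=7)


class TestInvariants:
    """Structural properties on random matrices, against a naive oracle."""

    @pytest.mark.parametrize("direction", ["left", "right"])
    def test_partition_order_consistency_on_random_matrices(self, direction):
        rng = np.random.default_rng(11)
        for _ in range(15):
            m = random_matrix(rng, 30, 60)
            start = int(rng.integers(0, 60))
            hst = build_uhst(m, start, direction)
            hst.validate()
            self._assert_partition_and_consistency(hst, m)
            assert sum(n.n for n in hst.leaves()) == m.n_haplotypes

    def test_bhst_partition_consistency_on_random_matrices(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            m = random_matrix(rng, 30, 60)
            hst = build_bhst(m, 30)
            hst.validate()
            self._assert_partition_and_consistency(hst, m)

    @staticmethod
    def _assert_partition_and_consistency(hst, m):
        for node in hst.nodes.values():
            if node.children:
                union = sorted(
                    i for c in node.children for i in hst.nodes[c].indexes.tolist()
                )
                assert union == sorted(node.indexes.tolist())
                sizes = [hst.nodes[c].n for c in node.children]
                assert sizes[0] == max(sizes)
            for mk, allele in node.haplotype:
                assert np.all(m.data[node.indexes, mk] == allele)
            # haplotype markers are contiguous
            markers = sorted(mk for mk, _ in node.haplotype)
            if markers:
                assert markers == list(range(markers[0], markers[-1] + 1))

    @pytest.mark.parametrize("direction", ["left", "right"])
    def test_divergence_matches_naive_consensus_scan(self, direction):
        rng = np.random.default_rng(17)
        for _ in range(10):
            m = random_matrix(rng, 25, 50)
            start = int(rng.integers(0, 50))
            hst = build_uhst(m, start, direction)
            assert majority_divergence_markers(hst) == naive_divergence(
                m.data, start, direction
            )

    def test_determinism(self, f1_matrix):
        a = build_bhst(f1_matrix, F1_START)
        b = build_bhst(f1_matrix, F1_START)
        assert {k: (v.haplotype, v.children, v.n) for k, v in a.nodes.items()} == {
            k: (v.haplotype, v.children, v.n) for k, v in b.nodes.items()
        }


def naive_divergence(data: np.ndarray, start: int, direction: str):
    """Independent oracle: for each row, first marker (scanning from start)
    where its allele differs from the consensus of rows still co-traveling
    with it (consensus ties break toward allele 0, as in the tree)."""
    step = 1 if direction == "right" else -1
    n, nm = data.shape
    out = {}
    for r in range(n):
        travelers = list(range(n))
        ptr = start
        div = None
        while 0 <= ptr < nm and len(travelers) > 1:
            col = data[travelers, ptr]
            if col.min() != col.max():
                counts = [int((col == 0).sum()), int((col == 1).sum())]
                maj = 0 if counts[0] >= counts[1] else 1
                if data[r, ptr] != maj:
                    div = ptr
                    break
                travelers = [t for t in travelers if data[t, ptr] == maj]
            ptr += step
        out[r] = div
    return out
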