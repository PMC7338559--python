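import numpy as np
import pytest

from assemblyscape import (CommunityTable, NullConfig, bmntd_matrix, bmntd_pair,
                           bnti_matrix, cophenetic_matrix, read_newick,
                           shuffle_tip_labels)
from tests.conftest import neutral_table


@pytest.fixture
def three_tip_dist(three_tip_tree):
    return cophenetic_matrix(three_tip_tree)


class TestCopheneticMatrix:
    def test_hand_path_sums(self, three_tip_dist):
        d = three_tip_dist.reorder(["A", "B", "C"]).data
        np.testing.assert_allclose(d, [[0, 2, 4], [2, 0, 4], [4, 4, 0]])

    def test_zero_diagonal(self, three_tip_dist):
        assert np.all(np.diag(three_tip_dist.data) == 0)

    def test_star_tree_equal_distances(self, tmp_path):
        p = tmp_path / "star.nwk"
        p.write_text("(A:1.5,B:1.5,C:1.5,D:1.5);\n")
        d = cophenetic_matrix(read_newick(p)).data
        off = d[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 3.0)


class TestBmntd:
    def test_identical_samples_zero(self, three_tip_dist):
        d = three_tip_dist.reorder(["A", "B", "C"]).data
        assert bmntd_pair([3, 1, 2], [3, 1, 2], d) == 0.0

    def test_single_taxon_pair(self, three_tip_dist):
        # A={A:1}, B={B:1}: each taxon's nearest neighbour is the other, d=2
        d = three_tip_dist.reorder(["A", "B", "C"]).data
        assert bmntd_pair([1, 0, 0], [0, 1, 0], d) == pytest.approx(2.0)

    def test_weighted_hand_example(self, three_tip_dist):
        # A={A:3,C:1}, B={B:1}: 0.5*[(0.75*2 + 0.25*4) + 1.0*2] = 2.25
        d = three_tip_dist.reorder(["A", "B", "C"]).data
        assert bmntd_pair([3, 0, 1], [0, 1, 0], d) == pytest.approx(2.25)

    def test_empty_sample_rejected(self, three_tip_dist):
        with pytest.raises(ValueError, match="empty"):
            bmntd_pair([0, 0, 0], [1, 0, 0], three_tip_dist.data)

    def test_matrix_identical_samples_all_zero(self, three_tip_dist):
        table = CommunityTable(["a", "b", "c"], ["A", "B", "C"],
                               np.tile([2, 1, 3], (3, 1)))
        np.testing.assert_allclose(bmntd_matrix(table, three_tip_dist), 0.0)

    def test_matrix_matches_brute_force(self):
        """Vectorized betaMNTD equals the per-pair loop on a random table."""
        from assemblyscape import simulate_tree
        rng = np.random.default_rng(42)
        tree = simulate_tree(10, seed=7)
        dist = cophenetic_matrix(tree)
        otus = [t.name for t in tree.tips()]
        counts = rng.integers(0, 6, size=(6, 10))
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = CommunityTable([f"s{i}" for i in range(6)], otus, counts)
        mat = bmntd_matrix(table, dist)
        d = dist.reorder(otus).data
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert mat[i, j] == pytest.approx(
                        bmntd_pair(counts[i], counts[j], d), abs=1e-12)

    def test_matrix_symmetric(self, three_tip_dist):
        rng = np.random.default_rng(0)
        table = CommunityTable(["a", "b", "c", "d"], ["A", "B", "C"],
                               rng.integers(1, 9, (4, 3)))
        mat = bmntd_matrix(table, three_tip_dist)
        np.testing.assert_allclose(mat, mat.T, atol=1e-15)


class TestShuffle:
    def test_multiset_conserved(self):
        rng = np.random.default_rng(3)
        d = rng.random((8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        shuffled = shuffle_tip_labels(d, np.random.default_rng(5))
        assert sorted(d.ravel()) == sorted(shuffled.ravel())

    def test_star_tree_invariant(self, tmp_path):
        p = tmp_path / "star.nwk"
        p.write_text("(A:1,B:1,C:1,D:1);\n")
        d = cophenetic_matrix(read_newick(p)).data
        np.testing.assert_allclose(shuffle_tip_labels(d, np.random.default_rng(1)), d)


class TestBnti:
    def test_star_phylogeny_degenerate(self, tmp_path):
        """Tip shuffles cannot move betaMNTD on a star tree -> flagged NaN."""
        p = tmp_path / "star.nwk"
        p.write_text("(A:1,B:1,C:1,D:1);\n")
        tree = read_newick(p)
        rng = np.random.default_rng(0)
        table = CommunityTable(["a", "b", "c"], ["A", "B", "C", "D"],
                               rng.integers(1, 9, (3, 4)))
        res = bnti_matrix(table, cophenetic_matrix(tree), NullConfig(n_reps=49, seed=1))
        iu = np.triu_indices(3, 1)
        assert res.degenerate[iu].all()
        assert np.isnan(res.bnti[iu]).all()

    def test_sample_reordering_invariance(self):
        """betaNTI is equivariant under sample reordering: the same pairs get
        the same values (tip shuffles act on OTUs, not samples)."""
        from assemblyscape import simulate_tree
        tree = simulate_tree(12, seed=3)
        otus = [t.name for t in tree.tips()]
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 20, (5, 12))
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = CommunityTable([f"s{i}" for i in range(5)], otus, counts)
        dist = cophenetic_matrix(tree)
        res1 = bnti_matrix(table, dist, NullConfig(n_reps=99, seed=5))
        order = rng.permutation(5)
        table2 = CommunityTable([table.sample_ids[k] for k in order], otus,
                                counts[order])
        res2 = bnti_matrix(table2, dist, NullConfig(n_reps=99, seed=5))
        np.testing.assert_allclose(res1.bnti[np.ix_(order, order)], res2.bnti,
                                   atol=1e-10)

    def test_otu_relabelling_invariance_of_bmntd(self):
        """The deterministic betaMNTD matrix is exactly invariant when OTU
        columns are reordered together with the distance matrix."""
        from assemblyscape import simulate_tree
        tree = simulate_tree(12, seed=3)
        otus = [t.name for t in tree.tips()]
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 20, (5, 12))
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = CommunityTable([f"s{i}" for i in range(5)], otus, counts)
        dist = cophenetic_matrix(tree)
        perm = rng.permutation(12)
        table2 = CommunityTable(table.sample_ids, [otus[k] for k in perm],
                                counts[:, perm])
        np.testing.assert_allclose(bmntd_matrix(table, dist),
                                   bmntd_matrix(table2, dist), atol=1e-12)

    def test_worker_count_independence(self):
        table, _ = neutral_table(n_samples=6, n_otus=40, depth=200, seed=4)
        from assemblyscape import simulate_tree
        tree = simulate_tree(40, seed=9)
        table = CommunityTable(table.sample_ids, [t.name for t in tree.tips()],
                               table.counts)
        dist = cophenetic_matrix(tree)
        r1 = bnti_matrix(table, dist, NullConfig(n_reps=40, seed=2, workers=1))
        r2 = bnti_matrix(table, dist, NullConfig(n_reps=40, seed=2, workers=4))
        np.testing.assert_array_equal(r1.bnti, r2.bnti)

    def test_bmntd_nonnegative_and_obs_equals_matrix(self, three_tip_dist):
        rng = np.random.default_rng(1)
        table = CommunityTable(["a", "b", "c"], ["A", "B", "C"],
                               rng.integers(1, 9, (3, 3)))
        res = bnti_matrix(table, three_tip_dist, NullConfig(n_reps=19, seed=0))
        assert (res.bmntd_obs >= 0).all()
        np.testing.assert_allclose(res.bmntd_obs,
                                   bmntd_matrix(table, three_tip_dist), atol=1e-12)
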