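import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from umed import (cophenetic_correlation, cut_tree, linkage_average, nmi,
                  s_dbw)
from umed.metrics import cophenetic_distances
from oracles import naive_nmi, naive_pearson, naive_sdbw, random_clustering


POINTS_1D = np.array([[0.0], [1.0], [10.0], [11.0]])


class TestLinkage:
    def test_hand_computed_upgma(self):
        Z = linkage_average(POINTS_1D)
        # (0,1) and (10,11) merge at height 1; final merge at the average
        # inter-set distance (9+10+10+11)/4 = 10.
        np.testing.assert_allclose(sorted(Z[:2, 2]), [1.0, 1.0])
        assert Z[2, 2] == pytest.approx(10.0)

    def test_duplicates_merge_at_height_zero(self):
        Z = linkage_average(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]]))
        assert Z[0, 2] == 0.0

    def test_needs_two_objects(self):
        with pytest.raises(ValueError):
            linkage_average(np.array([[1.0, 2.0]]))

    def test_deterministic_under_ties(self):
        # 3 collinear equidistant points: repeated runs give the same tree.
        X = np.array([[0.0], [1.0], [2.0]])
        trees = [linkage_average(X) for _ in range(5)]
        for Z in trees[1:]:
            np.testing.assert_array_equal(Z, trees[0])

    def test_cophenetic_ultrametric_inequality(self, rng):
        X = rng.standard_normal((25, 4))
        t = squareform(cophenetic_distances(linkage_average(X)))
        for i, j, k in itertools.combinations(range(25), 3):
            assert t[i, j] <= max(t[i, k], t[k, j]) + 1e-12


class TestCCC:
    def test_matches_direct_formula(self, rng):
        for _ in range(25):
            X = rng.standard_normal((int(rng.integers(5, 40)), 3))
            Z = linkage_average(X)
            expect = naive_pearson(pdist(X), cophenetic_distances(Z))
            assert cophenetic_correlation(X, Z) == pytest.approx(
                expect, abs=1e-12)

    def test_ultrametric_data_fixed_point(self):
        # Two zero-diameter blobs: distances are already ultrametric.
        X = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 10.0], [10.0, 10.0]])
        Z = linkage_average(X)
        assert cophenetic_correlation(X, Z) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_row_permutation(self, rng):
        X = rng.standard_normal((30, 5))
        base = cophenetic_correlation(X, linkage_average(X))
        perm = X[rng.permutation(30)]
        assert cophenetic_correlation(perm, linkage_average(perm)) == \
            pytest.approx(base, abs=1e-12)

    def test_degenerate_distances_rejected(self):
        X = np.ones((4, 2))  # all pairwise distances zero
        Z = linkage_average(X)
        with pytest.raises(ValueError, match="CCC undefined"):
            cophenetic_correlation(X, Z)


class TestCutTree:
    def test_extreme_cuts(self):
        Z = linkage_average(POINTS_1D)
        assert list(cut_tree(Z, 4)) == [1, 2, 3, 4]
        assert list(cut_tree(Z, 1)) == [1, 1, 1, 1]

    def test_two_groups_hand_computed(self):
        Z = linkage_average(POINTS_1D)
        assert list(cut_tree(Z, 2)) == [1, 1, 2, 2]

    def test_labels_first_appearance_order(self, rng):
        X = rng.standard_normal((40, 3))
        labels = cut_tree(linkage_average(X), 5)
        seen = []
        for lab in labels:
            if lab not in seen:
                seen.append(lab)
        assert seen == [1, 2, 3, 4, 5]

    def test_out_of_range(self):
        Z = linkage_average(POINTS_1D)
        for k in (0, 5):
            with pytest.raises(ValueError):
                cut_tree(Z, k)


class TestSDbw:
    def test_two_singletons_are_perfectly_separated(self):
        X = np.array([[0.0, 0.0], [5.0, 3.0]])
        assert s_dbw(X, np.array([1, 2])) == 0.0

    @pytest.mark.parametrize("variant", ["printed", "mean"])
    def test_matches_naive_oracle(self, rng, variant):
        for _ in range(30):
            n = int(rng.integers(8, 60))
            dims = int(rng.integers(1, 8))
            k = int(rng.integers(2, min(6, n // 2) + 1))
            X = rng.standard_normal((n, dims))
            labels = random_clustering(rng, n, k)
            scat, dens = naive_sdbw(X, labels, variant)
            assert s_dbw(X, labels, stdev_variant=variant) == pytest.approx(
                scat + dens, abs=1e-10)

    def test_between_density_nonincreasing_with_separation(self, rng):
        base = rng.standard_normal((30, 2)) * 0.8
        labels = np.array([1] * 15 + [2] * 15)
        dens = []
        for sep in (2.0, 4.0, 8.0, 16.0, 32.0):
            X = base.copy()
            X[15:, 0] += sep
            dens.append(naive_sdbw(X, labels)[1])
        assert all(a >= b - 1e-12 for a, b in zip(dens, dens[1:]))

    def test_k_must_be_at_least_two(self):
        X = np.arange(10.0).reshape(5, 2)
        with pytest.raises(ValueError):
            s_dbw(X, np.ones(5, dtype=int))

    def test_degenerate_dataset_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="degenerate dataset"):
            s_dbw(X, np.array([1, 1, 1, 2, 2, 2]))


class TestNMI:
    def test_identical_labelings(self):
        lab = [1, 1, 2, 2, 3]
        assert nmi(lab, lab) == pytest.approx(1.0)

    def test_constant_labeling_gives_zero(self):
        assert nmi([1, 1, 1, 1], [1, 2, 1, 2]) == 0.0
        assert nmi([2, 2], [7, 7]) == 0.0

    def test_matches_entropy_definitions(self, rng):
        a = random_clustering(rng, 30, 3)
        b = random_clustering(rng, 30, 3)
        assert nmi(a, b) == pytest.approx(naive_nmi(a, b), abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            nmi([1, 2], [1, 2, 3])
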