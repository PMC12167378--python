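"""Distance matrices and the max-min (bottleneck) grouping solvers."""

import itertools

import numpy as np
import pytest

from fluorosep.features import FeatureVectorSet
from fluorosep.pairing import (
    DistanceMatrix,
    Grouping,
    average_linkage_distance,
    bottleneck_grouping,
    compare_distance_matrices,
    embed_2d,
    enumerate_matchings,
    feature_distance_matrix,
    normalize_feature_space,
    optimal_grouping,
)


def brute_force_linkage(A, B):
    total = 0.0
    for a in A:
        for b in B:
            total += np.linalg.norm(np.asarray(a) - np.asarray(b))
    return total / (len(A) * len(B))


def brute_force_maxmin(dm: DistanceMatrix) -> float:
    """Independent recursion over pairings via itertools, no shared code."""
    labels = dm.labels

    def rec(rem):
        if not rem:
            return np.inf
        first = rem[0]
        best = -np.inf
        for k in range(1, len(rem)):
            d = dm.value(first, rem[k])
            rest = rem[1:k] + rem[k + 1:]
            best = max(best, min(d, rec(rest)))
        return best

    return rec(labels)


def random_dm(rng, n) -> DistanceMatrix:
    M = rng.random((n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels=[f"p{i}" for i in range(n)], D=D)


class TestAverageLinkage:
    def test_hand_example(self):
        assert average_linkage_distance([[0.0], [2.0]], [[4.0], [6.0]]) == pytest.approx(4.0)

    def test_identical_singletons(self):
        assert average_linkage_distance([[1.0, 2.0]], [[1.0, 2.0]]) == 0.0

    def test_matches_brute_force(self, rng):
        A = rng.standard_normal((5, 3))
        B = rng.standard_normal((7, 3))
        assert average_linkage_distance(A, B) == pytest.approx(
            brute_force_linkage(A, B), abs=1e-12)

    def test_empty_cluster(self):
        with pytest.raises(ValueError):
            average_linkage_distance(np.empty((0, 2)), [[1.0, 2.0]])


class TestDistanceMatrix:
    def test_two_proteins(self, rng):
        fvs = FeatureVectorSet({"a": rng.random((3, 2)), "b": rng.random((4, 2))})
        dm = feature_distance_matrix(fvs)
        assert dm.D.shape == (2, 2)
        assert dm.D[0, 1] == dm.D[1, 0] > 0
        assert dm.D[0, 0] == dm.D[1, 1] == 0

    def test_duplicated_cluster_nonzero_distance(self, rng):
        """Average linkage between identical clusters equals the cluster's
        mean pairwise distance — not zero."""
        arr = rng.standard_normal((6, 3))
        dm = feature_distance_matrix(FeatureVectorSet({"a": arr, "b": arr.copy()}))
        expected = brute_force_linkage(arr, arr)
        assert dm.D[0, 1] == pytest.approx(expected)
        assert dm.D[0, 1] > 0

    def test_ten_proteins_45_entries(self, rng):
        fvs = FeatureVectorSet({f"p{i}": rng.random((2, 4)) for i in range(10)})
        dm = feature_distance_matrix(fvs)
        iu = np.triu_indices(10, k=1)
        assert len(dm.D[iu]) == 45
        assert len(np.unique(dm.D[iu])) == 45

    def test_permutation_equivariant(self, rng):
        vecs = {f"p{i}": rng.random((3, 4)) for i in range(4)}
        dm = feature_distance_matrix(FeatureVectorSet(vecs))
        order = ["p2", "p0", "p3", "p1"]
        dm2 = feature_distance_matrix(
            FeatureVectorSet({k: vecs[k] for k in order}))
        for a, b in itertools.combinations(vecs, 2):
            assert dm.value(a, b) == pytest.approx(dm2.value(a, b))

    def test_csv_round_trip(self, rng, tmp_path):
        dm = random_dm(rng, 5)
        dm.to_csv(tmp_path / "d.csv")
        back = DistanceMatrix.from_csv(tmp_path / "d.csv")
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.D, dm.D)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], D=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestEnumerateMatchings:
    @pytest.mark.parametrize("n,count", [(4, 3), (6, 15), (10, 945)])
    def test_double_factorial_counts(self, n, count):
        labels = [f"p{i}" for i in range(n)]
        ms = list(enumerate_matchings(labels))
        assert len(ms) == count
        canon = {frozenset(frozenset(p) for p in m) for m in ms}
        assert len(canon) == count  # each matching appears exactly once

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError):
            list(enumerate_matchings(["a", "b", "c"]))


class TestOptimalGrouping:
    def test_four_protein_hand_example(self):
        """d(A,B)=d(C,D)=1, d(A,C)=d(B,D)=3, d(A,D)=d(B,C)=2: the best of
        the three matchings is {(A,C),(B,D)} with min distance 3."""
        D = np.array([
            [0.0, 1.0, 3.0, 2.0],
            [1.0, 0.0, 2.0, 3.0],
            [3.0, 2.0, 0.0, 1.0],
            [2.0, 3.0, 1.0, 0.0],
        ])
        g = optimal_grouping(DistanceMatrix(labels=list("ABCD"), D=D))
        assert g.min_distance == pytest.approx(3.0)
        assert {frozenset(p) for p in g.pairs} == {
            frozenset({"A", "C"}), frozenset({"B", "D"})}

    def test_all_equal_tie_break(self):
        D = np.ones((4, 4)) - np.eye(4)
        g = optimal_grouping(DistanceMatrix(labels=list("ABCD"), D=D))
        assert g.min_distance == pytest.approx(1.0)
        # deterministic canonical-first matching
        assert g.pairs == [("A", "B"), ("C", "D")]

    def test_matches_brute_force(self, rng):
        for n in (4, 6, 8):
            for _ in range(20):
                dm = random_dm(rng, n)
                g = optimal_grouping(dm)
                assert g.min_distance == pytest.approx(brute_force_maxmin(dm))

    def test_min_distance_dominates_all_matchings(self, rng):
        dm = random_dm(rng, 8)
        g = optimal_grouping(dm)
        for m in enumerate_matchings(dm.labels):
            assert g.min_distance >= min(dm.value(a, b) for a, b in m) - 1e-12

    def test_odd_rejected(self, rng):
        with pytest.raises(ValueError):
            optimal_grouping(random_dm(rng, 3))


class TestBottleneckGrouping:
    def test_agrees_with_exhaustive(self, rng):
        for n in (4, 6, 8, 10):
            for _ in range(10):
                dm = random_dm(rng, n)
                assert bottleneck_grouping(dm).min_distance == pytest.approx(
                    optimal_grouping(dm).min_distance)

    def test_forced_unique_optimum(self):
        """Star-like matrix where the unique max-min matching is forced."""
        D = np.array([
            [0.0, 10.0, 0.1, 0.1],
            [10.0, 0.0, 0.1, 0.1],
            [0.1, 0.1, 0.0, 10.0],
            [0.1, 0.1, 10.0, 0.0],
        ])
        g = bottleneck_grouping(DistanceMatrix(labels=list("ABCD"), D=D))
        assert {frozenset(p) for p in g.pairs} == {
            frozenset({"A", "B"}), frozenset({"C", "D"})}
        assert g.min_distance == pytest.approx(10.0)

    def test_all_equal(self):
        D = 2.5 * (np.ones((6, 6)) - np.eye(6))
        g = bottleneck_grouping(DistanceMatrix(labels=list("ABCDEF"), D=D))
        assert g.min_distance == pytest.approx(2.5)


class TestCompare:
    def test_affine_increasing(self, rng):
        dm = random_dm(rng, 5)
        dm2 = DistanceMatrix(labels=dm.labels, D=2.0 * dm.D + 0.5 * (1 - np.eye(5)))
        # keep diagonal zero and symmetry; correlation of upper triangles
        assert compare_distance_matrices(dm, dm2) == pytest.approx(1.0)

    def test_decreasing(self, rng):
        dm = random_dm(rng, 5)
        flipped = dm.D.max() + 0.1 - dm.D
        np.fill_diagonal(flipped, 0.0)
        dm2 = DistanceMatrix(labels=dm.labels, D=flipped)
        assert compare_distance_matrices(dm, dm2) == pytest.approx(-1.0)

    def test_matches_hand_loop(self, rng):
        d1, d2 = random_dm(rng, 6), random_dm(rng, 6)
        iu = np.triu_indices(6, k=1)
        x, y = d1.D[iu], d2.D[iu]
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean())**2).sum() * ((y - y.mean())**2).sum()))
        assert compare_distance_matrices(d1, d2) == pytest.approx(r_hand, abs=1e-12)

    def test_label_mismatch(self, rng):
        d1 = random_dm(rng, 4)
        d2 = DistanceMatrix(labels=["x0", "x1", "x2", "x3"], D=d1.D)
        with pytest.raises(ValueError):
            compare_distance_matrices(d1, d2)

    def test_too_small(self, rng):
        with pytest.raises(ValueError):
            compare_distance_matrices(random_dm(rng, 2), random_dm(rng, 2))


class TestEmbedding2D:
    def test_coordinates_shape_and_decoupling(self, rng):
        fvs = FeatureVectorSet({"a": rng.random((10, 6)), "b": rng.random((10, 6))})
        coords, labels = embed_2d(fvs, seed=0)
        assert coords.shape == (20, 2)
        assert labels.count("a") == 10
        # pairing output is independent of whether the embedding is run
        dm = feature_distance_matrix(fvs)
        dm2 = feature_distance_matrix(fvs)
        np.testing.assert_array_equal(dm.D, dm2.D)

    def test_seed_reproducible(self, rng):
        fvs = FeatureVectorSet({"a": rng.random((8, 4)), "b": rng.random((8, 4))})
        c1, _ = embed_2d(fvs, seed=5)
        c2, _ = embed_2d(fvs, seed=5)
        np.testing.assert_array_equal(c1, c2)


def test_normalize_feature_space(rng):
    fvs = FeatureVectorSet({"a": 5 * rng.random((4, 3)), "b": 5 * rng.random((4, 3))})
    scaled = normalize_feature_space(fvs)
    arrs, _ = scaled.all_vectors()
    norms = np.linalg.norm(arrs, axis=1)
    assert norms.max() == pytest.approx(1.0)
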