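"""LOF core: distances, neighborhoods, densities, scores.

The independent oracle is a literal, unoptimized triple-loop transcription
of the defining equations (reachability distance, LRD, LOF); the production
implementation must match it to 1e-9 relative error.  A second, external
cross-check uses scikit-learn's LocalOutlierFactor.
"""

import numpy as np
import pytest

from lofdetect import (
    ChannelMatrix,
    DistanceSpec,
    knn,
    lof_scores,
    natural_neighbor_k,
    pairwise_distance,
)
from lofdetect.errors import (
    DegenerateDimensionError,
    DegenerateGeometryWarning,
    InsufficientChannelsError,
    ParameterError,
)
from lofdetect.lof import local_reachability_density, reachability_distance


# ---------------------------------------------------------------- oracles

def brute_force_lof(D, k):
    """Literal transcription of the LOF definitions (independent oracle)."""
    n = D.shape[0]
    neighbors = []
    for p in range(n):
        others = [o for o in range(n) if o != p]
        others.sort(key=lambda o: (D[p, o], o))  # ties -> lower index
        neighbors.append(others[:k])
    k_distance = [D[p, neighbors[p][-1]] for p in range(n)]

    def reach(p, o):
        return max(k_distance[o], D[p, o])

    lrd = []
    for p in range(n):
        mean_reach = sum(reach(p, o) for o in neighbors[p]) / k
        lrd.append(1.0 / mean_reach if mean_reach >= 1e-12 else 1e12)
    lof = []
    for p in range(n):
        lof.append(sum(lrd[o] for o in neighbors[p]) / k / lrd[p])
    return np.array(lrd), np.array(lof)


def reference_natural_neighbor(D):
    """Independent transcription of the natural-neighbor search loop."""
    n = D.shape[0]
    order = []
    for p in range(n):
        others = [o for o in range(n) if o != p]
        others.sort(key=lambda o: (D[p, o], o))
        order.append(others)
    reverse = {p: set() for p in range(n)}
    prev_missing = None
    for r in range(1, n):
        for p in range(n):
            reverse[order[p][r - 1]].add(p)
        missing = sum(1 for p in range(n) if not reverse[p])
        if missing == 0 or missing == prev_missing:
            return r
        prev_missing = missing
    return n - 1


def random_matrix(rng, n_channels=None, n_samples=None):
    n_channels = n_channels or int(rng.integers(5, 20))
    n_samples = n_samples or int(rng.integers(10, 60))
    return ChannelMatrix(rng.standard_normal((n_channels, n_samples)), srate=100.0)


# ------------------------------------------------------------- distances

class TestPairwiseDistance:
    def test_3_4_5_triangle(self):
        X = ChannelMatrix(np.array([[0.0, 0.0], [3.0, 4.0]]), srate=1.0)
        D = pairwise_distance(X, DistanceSpec("euclidean"))
        assert D[0, 1] == pytest.approx(5.0)
        assert D[1, 0] == pytest.approx(5.0)
        assert D[0, 0] == 0.0

    def test_unit_scale_seuclidean_equals_euclidean(self, rng):
        X = random_matrix(rng)
        De = pairwise_distance(X, DistanceSpec("euclidean"))
        Ds = pairwise_distance(X, DistanceSpec("seuclidean", scale=np.ones(X.n_samples)))
        np.testing.assert_allclose(Ds, De, rtol=1e-12)

    def test_hand_matrix_against_double_loop(self):
        data = np.array([[1.0, 2.0, 0.5, -1.0],
                         [0.0, 1.0, 2.0, 3.0],
                         [-2.0, 0.5, 1.5, 0.0]])
        X = ChannelMatrix(data, srate=10.0)
        std = np.std(data, axis=0, ddof=1)
        for spec, scale in ((DistanceSpec("euclidean"), np.ones(4)), (DistanceSpec("seuclidean"), std)):
            D = pairwise_distance(X, spec)
            for i in range(3):
                for j in range(3):
                    expected = np.sqrt(sum(((data[i, t] - data[j, t]) / scale[t]) ** 2
                                           for t in range(4)))
                    assert D[i, j] == pytest.approx(expected, rel=1e-12)

    def test_symmetry_zero_diagonal(self, rng):
        X = random_matrix(rng)
        for metric in ("euclidean", "seuclidean"):
            D = pairwise_distance(X, DistanceSpec(metric))
            np.testing.assert_allclose(D, D.T)
            assert np.all(np.diag(D) == 0)
            assert np.all(D >= 0)

    def test_degenerate_dimension_raises_with_offender(self):
        data = np.array([[1.0, 5.0, 2.0], [2.0, 5.0, 1.0], [0.5, 5.0, 3.0]])
        X = ChannelMatrix(data, srate=1.0)
        with pytest.raises(DegenerateDimensionError) as err:
            pairwise_distance(X, DistanceSpec("seuclidean"))
        assert 1 in err.value.dimensions

    def test_explicit_zero_scale_rejected(self):
        with pytest.raises(DegenerateDimensionError):
            DistanceSpec("seuclidean", scale=np.array([1.0, 0.0, 1.0]))


# ------------------------------------------------------------------ knn

def line_distance_matrix(values):
    values = np.asarray(values, dtype=float)
    return np.abs(values[:, None] - values[None, :])


class TestKnn:
    def test_1d_example(self):
        D = line_distance_matrix([0.0, 1.0, 2.0, 10.0])
        nn = knn(D, 2)
        assert nn.k_distance[0] == pytest.approx(2.0)
        assert list(nn.neighbor_ids[0]) == [1, 2]

    def test_full_neighborhood(self, rng):
        X = random_matrix(rng, n_channels=7)
        D = pairwise_distance(X, DistanceSpec("euclidean"))
        nn = knn(D, 6)
        for c in range(7):
            assert set(nn.neighbor_ids[c]) == set(range(7)) - {c}

    def test_duplicates_have_zero_k_distance(self):
        D = np.zeros((3, 3))
        nn = knn(D, 1)
        assert np.all(nn.k_distance == 0)

    def test_tie_break_lower_index(self):
        # channels 1 and 2 equidistant from 0; the neighborhood takes index 1
        D = line_distance_matrix([0.0, 1.0, -1.0, 5.0])
        nn = knn(D, 1)
        assert nn.neighbor_ids[0][0] == 1

    def test_sorted_distances_and_invariants(self, rng):
        X = random_matrix(rng)
        D = pairwise_distance(X, DistanceSpec("euclidean"))
        for k in (1, 3, X.n_channels - 1):
            nn = knn(D, k)
            assert np.all(np.diff(nn.neighbor_dists, axis=1) >= 0)
            np.testing.assert_array_equal(nn.k_distance, nn.neighbor_dists[:, -1])
            for c in range(X.n_channels):
                assert c not in nn.neighbor_ids[c]

    @pytest.mark.parametrize("k", [0, 12, -1])
    def test_k_out_of_range(self, k):
        with pytest.raises(ParameterError):
            knn(np.zeros((12, 12)), k)


# ------------------------------------------------------ natural neighbors

class TestNaturalNeighborK:
    def test_matches_reference_on_two_clusters(self, rng):
        a = rng.normal(0, 0.1, size=(5, 8))
        b = rng.normal(50, 0.1, size=(5, 8))
        X = ChannelMatrix(np.vstack([a, b]), srate=1.0)
        D = pairwise_distance(X, DistanceSpec("euclidean"))
        assert natural_neighbor_k(D) == reference_natural_neighbor(D)

    def test_matches_reference_on_regular_spacing(self):
        D = line_distance_matrix(np.arange(10.0))
        assert natural_neighbor_k(D) == reference_natural_neighbor(D)

    def test_matches_reference_on_random_instances(self, rng):
        for _ in range(25):
            X = random_matrix(rng)
            D = pairwise_distance(X, DistanceSpec("euclidean"))
            assert natural_neighbor_k(D) == reference_natural_neighbor(D)

    def test_three_channels_in_range(self, rng):
        X = random_matrix(rng, n_channels=3)
        D = pairwise_distance(X, DistanceSpec("euclidean"))
        assert 1 <= natural_neighbor_k(D) <= 2

    def test_identical_channels_warn_k1(self):
        D = np.zeros((6, 6))
        with pytest.warns(DegenerateGeometryWarning):
            assert natural_neighbor_k(D) == 1


# ------------------------------------------- reachability / density / LOF

class TestReachabilityAndDensity:
    def test_reachability_examples(self):
        D = line_distance_matrix([0.0, 1.0, 2.0, 10.0])
        nn = knn(D, 2)
        # far pair: plain distance wins
        assert reachability_distance(3, 0, nn, D) == pytest.approx(10.0)
        # within the neighborhood: replaced by the k-distance of the target
        assert reachability_distance(1, 0, nn, D) == pytest.approx(2.0)

    def test_reachability_bounds(self, rng):
        X = random_matrix(rng)
        D = pairwise_distance(X, DistanceSpec("euclidean"))
        nn = knn(D, 3)
        for p in range(X.n_channels):
            for o in range(X.n_channels):
                if p == o:
                    continue
                r = reachability_distance(p, o, nn, D)
                assert r >= D[p, o] - 1e-15
                assert r >= nn.k_distance[o] - 1e-15

    def test_self_reachability_rejected(self):
        D = line_distance_matrix([0.0, 1.0, 2.0])
        nn = knn(D, 1)
        with pytest.raises(ParameterError):
            reachability_distance(1, 1, nn, D)

    def test_lrd_regular_spacing_interior(self):
        d = 0.7
        D = line_distance_matrix(np.arange(8) * d)
        nn = knn(D, 2)
        # interior point: both neighbors at reach-dist d
        assert local_reachability_density(4, nn, D) == pytest.approx(1.0 / d)

    def test_lrd_against_oracle_hand_matrix(self, rng):
        X = random_matrix(rng, n_channels=5, n_samples=12)
        D = pairwise_distance(X, DistanceSpec("euclidean"))
        nn = knn(D, 2)
        lrd_oracle, _ = brute_force_lof(D, 2)
        for p in range(5):
            assert local_reachability_density(p, nn, D) == pytest.approx(lrd_oracle[p], rel=1e-12)


class TestLofScores:
    def test_oracle_equivalence_50_instances(self, rng):
        for _ in range(50):
            n_ch = int(rng.integers(5, 65))
            n_s = int(rng.integers(10, 120))
            X = ChannelMatrix(rng.standard_normal((n_ch, n_s)), srate=100.0)
            metric = rng.choice(["euclidean", "seuclidean"])
            k = int(rng.integers(1, n_ch))
            spec = DistanceSpec(metric)
            D = pairwise_distance(X, spec)
            scores = lof_scores(X, spec, k=k)
            lrd_o, lof_o = brute_force_lof(D, k)
            np.testing.assert_allclose(scores.lof, lof_o, rtol=1e-9)
            np.testing.assert_allclose(scores.lrd, lrd_o, rtol=1e-9)

    def test_matches_sklearn(self, rng):
        from sklearn.neighbors import LocalOutlierFactor

        for _ in range(5):
            X = random_matrix(rng, n_channels=15, n_samples=40)
            k = int(rng.integers(2, 10))
            mine = lof_scores(X, DistanceSpec("euclidean"), k=k)
            sk = LocalOutlierFactor(n_neighbors=k, metric="euclidean")
            sk.fit(X.data)
            np.testing.assert_allclose(mine.lof, -sk.negative_outlier_factor_, rtol=1e-9)

    def test_regular_simplex_all_one(self):
        # orthonormal basis vectors: all pairwise distances sqrt(2)
        X = ChannelMatrix(np.eye(9), srate=1.0)
        for k in (1, 3, 8):
            scores = lof_scores(X, DistanceSpec("euclidean"), k=k)
            np.testing.assert_allclose(scores.lof, 1.0, atol=1e-9)

    def test_far_outlier_dominates(self, rng):
        cluster = rng.normal(0, 1.0, size=(20, 30))
        far = cluster.mean(axis=0) + 100 * 30**0.5  # ~100 cluster radii away
        X = ChannelMatrix(np.vstack([cluster, far]), srate=1.0)
        scores = lof_scores(X, DistanceSpec("euclidean"), k=3)
        assert np.argmax(scores.lof) == 20
        assert scores.lof[20] > 2.0
        assert np.all(scores.lof[:20] >= 0.8)
        assert np.all(scores.lof[:20] <= 1.3)

    def test_permutation_equivariance(self, rng):
        X = random_matrix(rng, n_channels=12)
        perm = rng.permutation(12)
        Xp = ChannelMatrix(X.data[perm], srate=X.srate,
                           labels=[X.labels[i] for i in perm])
        s = lof_scores(X, DistanceSpec("seuclidean"), k=4)
        sp = lof_scores(Xp, DistanceSpec("seuclidean"), k=4)
        np.testing.assert_allclose(sp.lof, s.lof[perm], rtol=1e-12)

    def test_euclidean_scale_invariance(self, rng):
        X = random_matrix(rng, n_channels=10)
        s1 = lof_scores(X, DistanceSpec("euclidean"), k=3)
        X2 = ChannelMatrix(X.data * 37.5, srate=X.srate, labels=X.labels)
        s2 = lof_scores(X2, DistanceSpec("euclidean"), k=3)
        np.testing.assert_allclose(s2.lof, s1.lof, rtol=1e-9)

    def test_duplicates_stay_finite(self):
        base = np.arange(6.0)
        data = np.vstack([base, base, base + 3, base - 2, base * 2])
        X = ChannelMatrix(data, srate=1.0)
        scores = lof_scores(X, DistanceSpec("euclidean"), k=2)
        assert np.all(np.isfinite(scores.lof))
        assert np.all(scores.lof > 0)
        assert np.all(scores.lrd > 0)

    def test_too_few_channels(self):
        X = ChannelMatrix(np.zeros((2, 5)) + np.arange(5), srate=1.0)
        with pytest.raises(InsufficientChannelsError):
            lof_scores(X, DistanceSpec("euclidean"), k=1)

    def test_auto_k_uses_natural_neighbors(self, rng):
        X = random_matrix(rng, n_channels=14)
        D = pairwise_distance(X, DistanceSpec("seuclidean"))
        scores = lof_scores(X, DistanceSpec("seuclidean"), k="auto")
        assert scores.k_used == reference_natural_neighbor(D)
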