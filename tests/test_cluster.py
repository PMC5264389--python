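import numpy as np
import pandas as pd
import pytest

from odorhab.cluster import (
    CentroidSet,
    CurveKMeans,
    build_habituation_space,
    cityblock_to_centroids,
    kmeans_curves,
    label_centroids,
    silhouette_profile,
)

from conftest import make_curves


def decay_family(rates, n_each, rng, n_samples=121, noise=0.01):
    """Normalized decay curves in len(rates) well-separated families."""
    t = np.arange(n_samples) * 0.25
    rows, membership = [], []
    for fam, lam in enumerate(rates):
        for _ in range(n_each):
            base = 0.3 + 0.7 * np.exp(-lam * t)
            rows.append(base + rng.normal(0, noise, size=n_samples))
            membership.append(fam)
    return np.vstack(rows), np.array(membership), t


class TestCurveKMeans:
    def test_recovers_two_separated_bundles(self):
        rng = np.random.default_rng(0)
        X, member, _ = decay_family([0.005, 0.2], 15, rng)
        km = CurveKMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        # same partition up to label permutation
        a = km.labels_[member == 0]
        b = km.labels_[member == 1]
        assert len(set(a)) == 1 and len(set(b)) == 1 and a[0] != b[0]

    def test_k1_centroid_is_pointwise_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 30))
        km = CurveKMeans(n_clusters=1, n_init=1, random_state=0).fit(X)
        assert np.allclose(km.cluster_centers_[0], X.mean(axis=0))

    def test_best_of_restarts_objective(self):
        rng = np.random.default_rng(2)
        X, _, _ = decay_family([0.01, 0.05, 0.3], 8, rng, noise=0.05)
        multi = CurveKMeans(n_clusters=3, n_init=20, random_state=5).fit(X)
        singles = [
            CurveKMeans(n_clusters=3, n_init=1, random_state=s).fit(X).inertia_
            for s in range(10)
        ]
        assert multi.inertia_ <= min(singles) + 1e-9

    def test_matches_reference_kmeans_objective(self):
        """Independent cross-check: the hand-rolled solver reaches the same
        within-cluster sum of squares as scikit-learn's on an easy problem."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(3)
        X, _, _ = decay_family([0.01, 0.08, 0.4], 10, rng, noise=0.02)
        mine = CurveKMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert mine.inertia_ == pytest.approx(ref.inertia_, rel=1e-6)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            CurveKMeans(n_clusters=5).fit(np.zeros((3, 4)))


def brute_silhouette(X, labels):
    """Textbook silhouette, O(n^2) loops, Euclidean distance."""
    n = len(X)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    svals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        a = d[i, same].mean() if same.any() else 0.0
        b = min(d[i, labels == k].mean() for k in set(labels) if k != labels[i])
        svals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(svals))


class TestSilhouette:
    def test_argmax_at_three_families(self):
        rng = np.random.default_rng(4)
        X, _, _ = decay_family([0.004, 0.03, 0.25], 12, rng, noise=0.02)
        prof = silhouette_profile(X, range(2, 6), n_restarts=10, seed=1)
        assert max(prof, key=prof.get) == 3

    def test_k_below_two_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        with pytest.raises(ValueError):
            silhouette_profile(X, [1, 2])

    def test_equidistant_degenerate_points_near_zero(self):
        # 6 points at the corners of a regular simplex-ish layout: any
        # 2-cluster split leaves cohesion ~ separation
        X = np.eye(6)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert abs(brute_silhouette(X, labels)) < 0.05

    def test_matches_brute_force_on_handmade_points(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 3))
        labels = np.array([0, 1, 0, 1, 0, 1])
        assert silhouette_score(X, labels) == pytest.approx(
            brute_silhouette(X, labels), abs=1e-12
        )


def _centroid_set(centroids, times=None):
    centroids = np.asarray(centroids, dtype=float)
    times = times if times is not None else np.arange(centroids.shape[1]) * 0.25
    return CentroidSet(
        centroids=centroids,
        assignment=np.zeros(centroids.shape[0], dtype=int),
        inertia=0.0,
        times=np.asarray(times, dtype=float),
    )


class TestLabelCentroids:
    def test_terminal_ordering(self):
        n = 481
        cs = _centroid_set([
            np.full(n, 0.5), np.full(n, 0.1), np.full(n, 0.9),
        ])
        labelled = label_centroids(cs)
        assert labelled.labels == {2: "low_hab", 0: "mid_hab", 1: "high_hab"}

    def test_flat_curve_is_low_habituation(self):
        n = 481
        t = np.arange(n) * 0.25
        cs = _centroid_set([
            np.full(n, 1.0),
            0.3 + 0.7 * np.exp(-0.02 * t),
            0.3 + 0.7 * np.exp(-0.2 * t),
        ], times=t)
        labelled = label_centroids(cs)
        assert labelled.labels[0] == "low_hab"
        assert labelled.labels[2] == "high_hab"

    def test_exact_tie_refused(self):
        cs = _centroid_set([np.full(10, 0.5)] * 3)
        with pytest.raises(ValueError, match="tie"):
            label_centroids(cs)

    def test_labels_follow_generative_decay_order(self):
        rng = np.random.default_rng(6)
        X, member, t = decay_family([0.004, 0.03, 0.25], 12, rng, noise=0.02)
        cs = label_centroids(kmeans_curves(X, 3, n_restarts=10, seed=1))
        # cluster holding the slow-decay family must be labelled low_hab
        for fam, expected in [(0, "low_hab"), (1, "mid_hab"), (2, "high_hab")]:
            votes = np.bincount(cs.assignment[member == fam]).argmax()
            assert cs.labels[int(votes)] == expected

    def test_requires_three_centroids(self):
        with pytest.raises(ValueError):
            label_centroids(_centroid_set(np.ones((2, 10))))


class TestCityblock:
    def _labelled(self, centroids):
        return label_centroids(_centroid_set(centroids))

    def test_identity_distance_zero(self):
        t = np.arange(481) * 0.25
        c = [0.3 + 0.7 * np.exp(-lam * t) for lam in (0.005, 0.03, 0.2)]
        cs = self._labelled(c)
        d = cityblock_to_centroids(np.array([c[0]]), cs)
        assert d.loc[0, "d_low"] == pytest.approx(0.0)

    def test_constant_offset_sums_samples(self):
        t = np.arange(481) * 0.25
        c = [0.3 + 0.7 * np.exp(-lam * t) for lam in (0.005, 0.03, 0.2)]
        cs = self._labelled(c)
        d = cityblock_to_centroids(np.array([c[1] + 0.1]), cs)
        assert d.loc[0, "d_mid"] == pytest.approx(48.1)

    def test_matches_loop_summed_oracle(self):
        rng = np.random.default_rng(7)
        cs = self._labelled(rng.normal(size=(3, 50)))
        x = rng.normal(size=50)
        d = cityblock_to_centroids(x[None, :], cs)
        for col, name in [("d_low", "low_hab"), ("d_mid", "mid_hab"), ("d_high", "high_hab")]:
            oracle = sum(abs(x[i] - cs.labelled_centroid(name)[i]) for i in range(50))
            assert d.loc[0, col] == pytest.approx(oracle, abs=1e-12)

    def test_metric_axioms_on_random_triples(self):
        from scipy.spatial.distance import cityblock

        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 30))
            assert cityblock(a, b) == pytest.approx(cityblock(b, a))
            assert cityblock(a, c) <= cityblock(a, b) + cityblock(b, c) + 1e-12

    def test_length_mismatch_rejected(self):
        cs = self._labelled(np.random.default_rng(0).normal(size=(3, 20)))
        with pytest.raises(ValueError, match="length"):
            cityblock_to_centroids(np.zeros((1, 19)), cs)


class TestHabituationSpace:
    def test_single_curve_coordinates_equal_distances(self):
        d = pd.DataFrame({
            "odorant_id": ["A", "B"],
            "d_low": [1.0, 2.0], "d_mid": [3.0, 4.0], "d_high": [5.0, 6.0],
        })
        space = build_habituation_space(d)
        assert space.loc["A"].tolist() == [1.0, 3.0, 5.0]

    def test_median_is_middle_order_statistic(self):
        d = pd.DataFrame({
            "odorant_id": ["A"] * 3,
            "d_low": [1.0, 9.0, 2.0], "d_mid": [0.0, 0.0, 0.0], "d_high": [7.0, 5.0, 6.0],
        })
        space = build_habituation_space(d)
        assert space.loc["A", "lowhab"] == 2.0
        assert space.loc["A", "highhab"] == 6.0

    def test_fast_decayers_sit_farther_from_low_centroid(self):
        rng = np.random.default_rng(9)
        X, member, t = decay_family([0.004, 0.25], 10, rng, noise=0.02)
        centroids = np.vstack([
            0.3 + 0.7 * np.exp(-lam * t) for lam in (0.004, 0.03, 0.25)
        ])
        cs = label_centroids(_centroid_set(centroids, t))
        d = cityblock_to_centroids(X, cs)
        d["odorant_id"] = np.where(member == 0, "slow", "fast")
        space = build_habituation_space(d)
        assert space.loc["fast", "lowhab"] > space.loc["slow", "lowhab"]
        assert space.loc["fast", "highhab"] < space.loc["slow", "highhab"]
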