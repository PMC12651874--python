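"""K-means, indices and DBSCAN against brute-force and sklearn oracles."""

from itertools import product

import numpy as np
import pytest

from copmech.clustering import (bootstrap_indices, calinski_harabasz,
                                cluster_descriptives, davies_bouldin, dbscan,
                                elbow_curve, internal_indices, kmeans,
                                silhouette_mean)

from conftest import canonical_partition


def _exhaustive_best_wcss(X, k):
    """Global WCSS minimum by enumerating all k-partitions (tiny n only)."""
    n = len(X)
    best = np.inf
    for assignment in product(range(k), repeat=n):
        labels = np.array(assignment)
        if len(np.unique(labels)) < k:
            continue
        w = sum(float(np.sum((X[labels == j] - X[labels == j].mean(axis=0)) ** 2))
                for j in range(k))
        best = min(best, w)
    return best


class TestKMeans:
    def test_matches_exhaustive_partition_optimum(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (4, 2)), rng.normal(5, 0.5, (4, 2))])
        res = kmeans(X, 2, n_init=10, seed=0)
        assert res.wcss == pytest.approx(_exhaustive_best_wcss(X, 2), rel=1e-9)
        assert canonical_partition(res.labels) == [0, 0, 0, 0, 1, 1, 1, 1]

    def test_three_clusters_exhaustive(self, rng):
        X = rng.standard_normal((7, 2))
        res = kmeans(X, 3, n_init=30, seed=1)
        assert res.wcss == pytest.approx(_exhaustive_best_wcss(X, 3), rel=1e-9)

    def test_k_equals_n_gives_zero_wcss(self, rng):
        X = rng.standard_normal((6, 2))
        assert kmeans(X, 6, seed=0).wcss == pytest.approx(0.0, abs=1e-12)

    def test_centroids_are_member_means(self, rng):
        X = rng.standard_normal((20, 3))
        res = kmeans(X, 4, seed=2)
        for j in range(4):
            np.testing.assert_allclose(res.centroids[j],
                                       X[res.labels == j].mean(axis=0),
                                       atol=1e-12)

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError, match="k must lie"):
            kmeans(rng.standard_normal((4, 2)), 5)

    def test_matches_sklearn_on_blobs(self, rng):
        from sklearn.cluster import KMeans

        X = np.vstack([rng.normal(c, 0.4, (10, 2)) for c in (0, 6, 12)])
        ours = kmeans(X, 3, n_init=10, seed=0)
        sk = KMeans(3, n_init=10, random_state=0).fit(X)
        assert ours.wcss == pytest.approx(sk.inertia_, rel=1e-9)


class TestElbow:
    def test_wcss_non_increasing(self, rng):
        X = rng.standard_normal((15, 2))
        res = elbow_curve(X, range(1, 8), n_init=10, seed=0)
        diffs = np.diff(res.wcss)
        assert np.all(diffs <= 1e-9)

    def test_k1_is_total_scatter(self, rng):
        X = rng.standard_normal((10, 3))
        res = elbow_curve(X, [1], seed=0)
        assert res.wcss[0] == pytest.approx(
            float(np.sum((X - X.mean(axis=0)) ** 2)))
        assert res.knee is None

    def test_knee_found_on_three_blobs(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = np.vstack([r.normal(c, 0.3, (8, 2))
                           for c in ((0, 0), (6, 0), (0, 6))])
            if elbow_curve(X, range(1, 7), seed=seed).knee == 3:
                hits += 1
        assert hits >= 18


class TestIndices:
    def _brute_silhouette(self, X, labels):
        n = len(X)
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        s = []
        for i in range(n):
            own = [j for j in range(n) if labels[j] == labels[i] and j != i]
            if not own:
                s.append(0.0)
                continue
            a = np.mean([d[i, j] for j in own])
            b = min(np.mean([d[i, j] for j in range(n) if labels[j] == c])
                    for c in set(labels) if c != labels[i])
            s.append((b - a) / max(a, b))
        return float(np.mean(s))

    def test_all_indices_match_double_loop_oracle(self, rng):
        X = rng.standard_normal((6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert silhouette_mean(X, labels) == pytest.approx(
            self._brute_silhouette(X, labels), abs=1e-12)
        from sklearn.metrics import (calinski_harabasz_score,
                                     davies_bouldin_score, silhouette_score)

        assert silhouette_mean(X, labels) == pytest.approx(
            silhouette_score(X, labels), abs=1e-12)
        assert davies_bouldin(X, labels) == pytest.approx(
            davies_bouldin_score(X, labels), abs=1e-12)
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels), abs=1e-9)

    def test_tight_far_blobs_approach_limits(self, rng):
        X = np.vstack([rng.normal(0, 0.01, (5, 2)),
                       rng.normal(100, 0.01, (5, 2))])
        labels = np.array([0] * 5 + [1] * 5)
        rep = internal_indices(X, labels)
        assert rep.silhouette > 0.95
        assert rep.davies_bouldin < 0.05

    def test_singleton_cluster_scores_zero_silhouette(self):
        X = np.array([[0.0, 0.0], [100.0, 0.0], [101.0, 0.0], [99.0, 0.0]])
        labels = np.array([0, 1, 1, 1])
        # singleton contributes 0; the rest are near 1
        assert 0.5 < silhouette_mean(X, labels) < 1.0

    def test_single_cluster_undefined(self, rng):
        with pytest.raises(ValueError, match="single cluster"):
            internal_indices(rng.standard_normal((5, 2)), np.zeros(5, int))


class TestBootstrapIndices:
    def test_separated_blobs_high_ci_containing_point_estimate(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (10, 2)),
                       rng.normal(8, 0.3, (10, 2))])
        rep = bootstrap_indices(X, 2, B=200, seed=0)
        lo, hi = rep.silhouette_ci
        assert lo > 0.7
        assert lo <= rep.silhouette <= hi

    def test_duplicated_points_give_degenerate_indices(self):
        """Two stacks of identical points: Davies-Bouldin is exactly 0 in
        every replicate (zero scatter), and the full-data silhouette is 1.
        (Silhouette replicates can dip when a resample leaves a singleton,
        which scores 0 by convention.)"""
        X = np.vstack([np.tile([0.0, 0.0], (6, 1)), np.tile([5.0, 5.0], (6, 1))])
        rep = bootstrap_indices(X, 2, B=50, seed=1)
        assert rep.davies_bouldin_ci == (0.0, 0.0)
        assert rep.silhouette == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self, rng):
        X = rng.standard_normal((14, 2)) + np.repeat([[0], [6]], 7, axis=0)
        a = bootstrap_indices(X, 2, B=60, seed=9)
        b = bootstrap_indices(X, 2, B=60, seed=9)
        assert a.silhouette_ci == b.silhouette_ci
        assert a.davies_bouldin_ci == b.davies_bouldin_ci


class TestDBSCAN:
    def _brute_oracle(self, X, eps, min_samples):
        """Reachability-closure oracle: grow clusters from core points by
        repeated closure over eps-neighborhoods."""
        n = len(X)
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        neigh = [set(np.nonzero(d[i] <= eps)[0]) for i in range(n)]
        core = [len(neigh[i]) >= min_samples for i in range(n)]
        labels = [-1] * n
        cid = 0
        for i in range(n):
            if labels[i] != -1 or not core[i]:
                continue
            members = {i}
            changed = True
            while changed:
                changed = False
                for j in list(members):
                    if core[j]:
                        new = neigh[j] - members
                        if new:
                            members |= new
                            changed = True
            for j in members:
                labels[j] = cid
            cid += 1
        return labels

    def test_matches_reachability_closure_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((12, 2))
            for eps in (0.5, 0.9, 1.4):
                ours = dbscan(X, eps=eps, min_samples=2)
                oracle = self._brute_oracle(X, eps, 2)
                assert canonical_partition(ours) == canonical_partition(oracle)

    def test_all_close_points_form_one_cluster(self, rng):
        X = 0.01 * rng.standard_normal((8, 2))
        labels = dbscan(X, eps=0.687, min_samples=2)
        assert set(labels) == {0}

    def test_isolated_point_is_noise(self, rng):
        X = np.vstack([0.05 * rng.standard_normal((6, 2)), [[50.0, 50.0]]])
        labels = dbscan(X, eps=0.687, min_samples=2)
        assert labels[-1] == -1

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="eps"):
            dbscan(np.zeros((3, 2)), eps=0.0)


class TestDescriptives:
    def test_two_point_cluster_formulas(self):
        Y = np.array([[1.0, 10.0], [3.0, 14.0], [50.0, 50.0]])
        labels = np.array([0, 0, 1])
        st = cluster_descriptives(Y, labels)
        np.testing.assert_allclose(st.means[0], [2.0, 12.0])
        np.testing.assert_allclose(st.variances[0], [2.0, 8.0])  # (a-b)^2/2
        assert st.sizes == [2, 1]
        np.testing.assert_allclose(st.variances[1], [0.0, 0.0])

    def test_sizes_partition_n(self, rng):
        Y = rng.standard_normal((23, 2))
        labels = rng.integers(0, 4, 23)
        st = cluster_descriptives(Y, labels)
        assert sum(st.sizes) == 23
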