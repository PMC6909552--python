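"""Pearson distance, z-scores, agglomeration, centroids, peak ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import budphase as bp
from budphase.containers import BudphaseError


def brute_force_pearson_distance(x):
    """Two-pass correlation oracle, gene pair by gene pair."""
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            xi = x[i] - x[i].mean()
            xj = x[j] - x[j].mean()
            r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            d[i, j] = 1 - r
    np.fill_diagonal(d, 0.0)
    return d


def naive_complete_linkage(dist, k):
    """O(n^3) agglomeration oracle: repeatedly merge the pair of clusters
    with the smallest maximum inter-point distance; ties by smallest
    member-index pair."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dmax = max(dist[i, j] for i in clusters[a]
                           for j in clusters[b])
                key = (dmax, min(clusters[a] + clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters):
        labels[members] = lab
    return labels


class TestPearsonDistance:
    def test_affine_invariance(self):
        x = pd.DataFrame([[1.0, 2, 3, 4], [7.0, 9, 11, 13]],
                         index=["a", "b"])
        d = bp.pearson_distance(x)
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelation(self):
        x = pd.DataFrame([[1.0, 2, 3], [-1.0, -2, -3]], index=["a", "b"])
        assert bp.pearson_distance(x).loc["a", "b"] == pytest.approx(2.0)

    def test_hand_value(self):
        x = pd.DataFrame([[1.0, 2, 3], [1.0, 3, 2]], index=["a", "b"])
        assert bp.pearson_distance(x).loc["a", "b"] == pytest.approx(0.5)

    def test_zero_variance_named(self):
        x = pd.DataFrame([[1.0, 1, 1], [1.0, 2, 3]], index=["flat", "ok"])
        with pytest.raises(BudphaseError, match="flat"):
            bp.pearson_distance(x)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(20, 8))
        x += np.linspace(0, 1, 8)  # avoid accidental zero variance
        d = bp.pearson_distance(pd.DataFrame(x)).to_numpy()
        np.testing.assert_allclose(d, brute_force_pearson_distance(x),
                                   atol=1e-12)
        assert d.min() >= 0 and d.max() <= 2


class TestZscore:
    def test_simple_row(self):
        z = bp.zscore(pd.DataFrame([[1.0, 2, 3]], index=["g"]))
        np.testing.assert_allclose(z.loc["g"], [-1, 0, 1], atol=1e-12)

    def test_hand_row_sample_sd(self):
        z = bp.zscore(pd.DataFrame([[10.0, 10, 40]], index=["g"]))
        np.testing.assert_allclose(
            z.loc["g"], [-0.57735, -0.57735, 1.154701], atol=1e-5)

    def test_population_sd_option(self):
        z = bp.zscore(pd.DataFrame([[1.0, 2, 3]], index=["g"]), ddof=0)
        np.testing.assert_allclose(
            z.loc["g"], [-1.224745, 0, 1.224745], atol=1e-6)

    def test_constant_row_rejected(self):
        with pytest.raises(BudphaseError):
            bp.zscore(pd.DataFrame([[2.0, 2, 2]], index=["g"]))

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 100_000))
    def test_rows_standardized(self, seed):
        rng = np.random.default_rng(seed)
        z = bp.zscore(pd.DataFrame(rng.normal(size=(15, 9))))
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)


class TestHierarchicalClusters:
    def test_planted_two_groups(self):
        rng = np.random.default_rng(0)
        a = np.sin(np.linspace(0, 3, 10))
        b = np.cos(np.linspace(0, 3, 10))
        x = np.vstack([a + rng.normal(0, 0.01, 10) for _ in range(5)]
                      + [b + rng.normal(0, 0.01, 10) for _ in range(5)])
        clusterer = bp.ProfileClusterer(n_clusters=2)
        labels = clusterer.fit_predict(pd.DataFrame(x))
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels.iloc[0] != labels.iloc[5]

    def test_k_equals_n_singletons(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(6, 5)))
        labels = bp.ProfileClusterer(n_clusters=6).fit_predict(x)
        assert labels.nunique() == 6

    def test_k_one(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(6, 5)))
        labels = bp.ProfileClusterer(n_clusters=1).fit_predict(x)
        assert labels.nunique() == 1

    def test_k_above_n_rejected(self):
        x = pd.DataFrame(np.random.default_rng(3).normal(size=(4, 5)))
        with pytest.raises(BudphaseError):
            bp.ProfileClusterer(n_clusters=5).fit(x)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle(self, seed):
        """Complete linkage agrees with the O(n^3) oracle on random
        distances (continuous values, so no linkage ties)."""
        rng = np.random.default_rng(seed)
        n, k = 12, 4
        x = rng.normal(size=(n, 7))
        dist = bp.pearson_distance(pd.DataFrame(x))
        got = bp.hierarchical_clusters(dist, k=k).to_numpy()
        expected = naive_complete_linkage(dist.to_numpy(), k)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(got, expected) == pytest.approx(1.0)

    def test_tpm_and_zscore_partitions_coincide(self):
        """Pearson distance is affine-invariant per gene, so clustering
        TPM rows and z-scored rows gives the same partition."""
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.lognormal(2, 1, size=(25, 10)))
        labels_tpm = bp.ProfileClusterer(n_clusters=5).fit_predict(x)
        labels_z = bp.ProfileClusterer(n_clusters=5).fit_predict(bp.zscore(x))
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels_tpm, labels_z) == pytest.approx(1.0)


def _meta_for(columns):
    rows = []
    for c in columns:
        date, rep = c.rsplit("_", 1)
        rows.append({"sample_id": c, "cultivar": "cv", "tree": rep,
                     "date": date, "stage": pd.NA})
    return bp.validate_metadata(pd.DataFrame(rows))


class TestCentroids:
    def _z_and_meta(self):
        cols = [f"2015-0{m}-15_t{r}" for m in (7, 8, 9) for r in (1, 2)]
        z = pd.DataFrame(
            [[1.0, 1.0, 0.0, 0.0, -1.0, -1.0],
             [-1.0, -1.0, 0.0, 0.0, 1.0, 1.0],
             [1.0, 1.0, 0.2, -0.2, -1.0, -1.0]],
            index=["g1", "g2", "g3"], columns=cols)
        return z, _meta_for(cols)

    def test_single_gene_cluster_is_its_profile(self):
        z, meta = self._z_and_meta()
        assignment = pd.Series([1, 2, 2], index=z.index)
        cent = bp.cluster_centroids(z, assignment, meta)
        np.testing.assert_allclose(cent.loc[1], [1.0, 0.0, -1.0], atol=1e-12)

    def test_symmetric_genes_cancel(self):
        z, meta = self._z_and_meta()
        assignment = pd.Series([1, 1, 2], index=z.index)
        cent = bp.cluster_centroids(z, assignment, meta)
        np.testing.assert_allclose(cent.loc[1], [0.0, 0.0, 0.0], atol=1e-12)

    def test_peak_order_hand_case(self):
        cent = pd.DataFrame([[0, 0, 0, 0, 1.0],
                             [1.0, 0, 0, 0, 0],
                             [0, 0, 1.0, 0, 0]], index=[1, 2, 3])
        mapping = bp.order_clusters_by_peak(cent)
        assert mapping == {2: 1, 3: 2, 1: 3}

    def test_peak_order_identity(self):
        cent = pd.DataFrame(np.eye(3), index=[1, 2, 3])
        assert bp.order_clusters_by_peak(cent) == {1: 1, 2: 2, 3: 3}

    def test_peak_tie_larger_cluster_first(self):
        cent = pd.DataFrame([[0, 1.0, 0.5], [0, 1.0, 0.4]], index=[1, 2])
        assignment = pd.Series([1] * 3 + [2] * 10,
                               index=[f"g{i}" for i in range(13)])
        mapping = bp.order_clusters_by_peak(cent, assignment)
        assert mapping == {2: 1, 1: 2}

    def test_centroid_correlation_extremes(self):
        z, meta = self._z_and_meta()
        assignment = pd.Series([1, 1, 1], index=z.index)
        cent = bp.cluster_centroids(z, assignment.iloc[:1], meta)
        corrs = bp.centroid_correlations(z, cent, assignment, meta)
        assert corrs["g1"] == pytest.approx(1.0)
        assert corrs["g2"] == pytest.approx(-1.0)
        assert corrs["g3"] == pytest.approx(1.0)


class TestPlantedRecovery:
    def test_planted_cluster_ari(self, default_run):
        """End-to-end: the default synthetic dataset's planted clusters
        are recovered at ARI >= 0.8."""
        result, _ = default_run
        assert result.metrics["cluster_ari"] >= 0.8

    def test_relabeled_peaks_nondecreasing(self, default_run):
        result, _ = default_run
        peaks = result.centroids.to_numpy().argmax(axis=1)
        # ordering used the reference cultivar; across-cultivar centroids
        # may locally disagree, but peaks must be sorted overall trend-wise
        assert (np.diff(peaks) >= -1).all()

    def test_planted_marker_high_correlation(self, default_run):
        result, dataset = default_run
        marker_corrs = result.corrs.reindex(
            [dataset.truth.marker_genes[c] for c in (1, 4, 5, 7, 8, 9, 10)])
        assert (marker_corrs.dropna() > 0.9).all()
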