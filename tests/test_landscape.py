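import numpy as np
import pytest
from sklearn.datasets import make_blobs

from dockselect import (
    FeatureTable,
    LatentModel,
    SelectorConfig,
    SelectorModel,
    cluster_algorithms,
    cluster_instances,
    cluster_profiles,
    embed_instances,
    factorize,
    feature_importance,
    fit_selector,
    rank_transform,
    reduce_portfolio,
)
from sklearn.ensemble import RandomForestRegressor

from conftest import perf_from_array


def blob_table(centers, n=120, cluster_std=0.6, seed=0, d=2):
    X, _ = make_blobs(
        n_samples=n, centers=centers, cluster_std=cluster_std, n_features=d,
        random_state=seed,
    )
    return FeatureTable(
        values=X,
        row_ids=tuple(f"i{i}" for i in range(n)),
        feature_names=tuple(f"f{j}" for j in range(d)),
    )


class TestFeatureImportance:
    def test_sums_to_one_and_descending(self, small_benchmark, small_ranks, small_selector_config):
        model = fit_selector(
            small_benchmark.descriptor_features, small_ranks, small_selector_config
        )
        imp = feature_importance(model)
        assert imp.sum() == pytest.approx(1.0)
        assert (imp.values >= 0).all()
        assert (np.diff(imp.values) <= 1e-12).all()

    def test_planted_signal_feature_ranks_first(self, small_benchmark, small_ranks, small_selector_config):
        model = fit_selector(
            small_benchmark.descriptor_features, small_ranks, small_selector_config
        )
        imp = feature_importance(model)
        assert imp.index[0].startswith("desc_inf")

    def test_pure_noise_importances_near_uniform(self, small_perf):
        rng = np.random.default_rng(0)
        d = 40
        ranks = rank_transform(small_perf)
        noise = FeatureTable(
            values=rng.uniform(size=(len(ranks.row_ids), d)),
            row_ids=ranks.row_ids,
            feature_names=tuple(f"f{j}" for j in range(d)),
        )
        model = fit_selector(noise, ranks, SelectorConfig(k=3, n_trees=100, seed=0))
        imp = feature_importance(model)
        assert imp.max() < 5.0 / d
        assert imp.max() - imp.min() < 5.0 / d

    def test_unfitted_model_rejected(self):
        model = SelectorModel(
            regressor=RandomForestRegressor(n_estimators=3),
            algorithm_factors=np.eye(2),
            feature_names=("f",),
            algorithm_ids=("A1", "A2"),
            train_mean_ranks=np.array([1.0, 2.0]),
            config=SelectorConfig(k=2),
        )
        with pytest.raises(ValueError, match="fitted"):
            feature_importance(model)


def latent_from(values, k):
    return factorize(rank_transform(perf_from_array(values)), k=k)


class TestClusterAlgorithms:
    def test_identical_columns_merge_first_at_height_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(20, 1))
        values = np.hstack([base, base, base + 5.0])
        latent = latent_from(values, k=2)
        link = cluster_algorithms(latent)
        merges = link.merge_list()
        assert merges.loc[0, "height"] == pytest.approx(0.0, abs=1e-9)
        assert {merges.loc[0, "left"], merges.loc[0, "right"]} == {0, 1}

    def test_heights_non_decreasing(self, small_ranks):
        link = cluster_algorithms(factorize(small_ranks, k=4))
        heights = link.merge_list()["height"].to_numpy()
        assert (np.diff(heights) >= -1e-12).all()

    def test_sign_flip_invariance(self, small_ranks):
        latent = factorize(small_ranks, k=3)
        flip = np.array([1.0, -1.0, -1.0])
        flipped = LatentModel(
            instance_factors=latent.instance_factors * flip,
            algorithm_factors=latent.algorithm_factors * flip,
            singular_values=latent.singular_values,
            row_ids=latent.row_ids,
            col_ids=latent.col_ids,
        )
        np.testing.assert_allclose(
            cluster_algorithms(latent).merges, cluster_algorithms(flipped).merges,
            atol=1e-9,
        )

    def test_single_algorithm_rejected(self):
        latent = LatentModel(
            instance_factors=np.ones((3, 1)),
            algorithm_factors=np.ones((1, 1)),
            singular_values=np.array([1.0]),
            row_ids=("a", "b", "c"),
            col_ids=("A1",),
        )
        with pytest.raises(ValueError, match="at least 2"):
            cluster_algorithms(latent)


class TestReducePortfolio:
    def _link(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(30, 1))
        # A1 ~ A2 (identical), A3 ~ A4 (identical), A5 distant
        values = np.hstack([base, base, base + 3, base + 3, -base * 2])
        return cluster_algorithms(latent_from(values, k=3))

    def test_pair_representative_has_lower_mean_rank(self):
        link = self._link()
        ranks = {"A1": 2.0, "A2": 1.0, "A3": 3.0, "A4": 4.0, "A5": 5.0}
        kept = reduce_portfolio(link, ranks, level="lowest_pairs")
        assert "A2" in kept and "A1" not in kept
        assert "A3" in kept and "A4" not in kept
        assert "A5" in kept

    def test_size_equals_cluster_count_and_subset_of_portfolio(self):
        link = self._link()
        ranks = {a: i for i, a in enumerate(link.algorithm_ids)}
        kept = reduce_portfolio(link, ranks, level="lowest_pairs")
        assert len(kept) == 3  # two pairs + one singleton
        assert set(kept) <= set(link.algorithm_ids)
        higher = reduce_portfolio(link, ranks, level="one_higher")
        assert len(higher) <= len(kept)

    def test_all_singletons_identity(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(25, 4)) * [1, 10, 100, 1000]
        link = cluster_algorithms(latent_from(values, k=3))
        # no zero-height leaf pairs exist when no columns coincide, but pairs
        # may still form; identity holds when every cluster is a singleton
        from dockselect.landscape import _linkage_clusters

        clusters = _linkage_clusters(link, "lowest_pairs")
        if all(len(c) == 1 for c in clusters):
            kept = reduce_portfolio(link, {a: 0 for a in link.algorithm_ids})
            assert kept == list(link.algorithm_ids)

    def test_tie_breaks_by_portfolio_order(self):
        link = self._link()
        ranks = {a: 1.0 for a in link.algorithm_ids}
        kept = reduce_portfolio(link, ranks, level="lowest_pairs")
        assert "A1" in kept and "A3" in kept


class TestEmbedInstances:
    def test_pca_on_2d_data_preserves_pairwise_distances(self):
        t = blob_table(centers=[[0, 0], [6, 6]], n=40, seed=3)
        emb = embed_instances(t, method="pca")
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(emb.coords), pdist(t.values), atol=1e-8)

    def test_pca_separates_blobs_along_pc1(self):
        t = blob_table(centers=[[0, 0, 0], [10, 0, 0]], n=80, d=3, seed=4)
        emb = embed_instances(t, method="pca")
        labels = (t.values[:, 0] > 5).astype(int)
        within = max(emb.coords[labels == c][:, 0].std() for c in (0, 1))
        between = abs(
            emb.coords[labels == 0][:, 0].mean() - emb.coords[labels == 1][:, 0].mean()
        )
        assert between > 3 * within

    def test_tsne_deterministic_for_fixed_seed(self):
        t = blob_table(centers=[[0, 0], [8, 8]], n=60, seed=5)
        a = embed_instances(t, method="tsne", seed=11)
        b = embed_instances(t, method="tsne", seed=11)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_single_feature_rejected(self):
        t = FeatureTable(values=np.ones((5, 1)), row_ids=tuple("abcde"), feature_names=("f",))
        with pytest.raises(ValueError, match="2 features"):
            embed_instances(t)


class TestClusterInstances:
    def test_two_blob_recovery_with_high_silhouette(self):
        t = blob_table(centers=[[0, 0], [12, 12]], n=120, seed=6)
        report = cluster_instances(t, k_range=(2, 15), seed=0)
        assert report.best_k == 2
        assert report.silhouettes[2] > 0.7

    def test_four_blob_recovery(self):
        centers = [[0, 0], [12, 0], [0, 12], [12, 12]]
        t = blob_table(centers=centers, n=160, seed=7)
        report = cluster_instances(t, k_range=(2, 15), seed=0)
        assert report.best_k == 4

    def test_best_k_is_argmax_of_scan(self, small_benchmark):
        t = small_benchmark.descriptor_features
        report = cluster_instances(t, k_range=(2, 6), seed=1)
        assert report.best_k == int(report.silhouettes.idxmax())
        assert report.silhouettes.between(-1, 1).all()

    def test_too_few_instances_rejected(self):
        t = blob_table(centers=[[0, 0]], n=10, seed=8)
        with pytest.raises(ValueError, match="more than"):
            cluster_instances(t, k_range=(2, 15))


class TestClusterProfiles:
    def test_identical_rows_have_zero_iqr(self):
        t = FeatureTable(
            values=np.tile([1.0, 5.0], (6, 1)),
            row_ids=tuple(f"i{i}" for i in range(6)),
            feature_names=("a", "b"),
        )
        profile = cluster_profiles(t, np.zeros(6, dtype=int))
        assert (profile["q3"] - profile["q1"] == 0).all()
        assert (profile["n_outliers"] == 0).all()

    def test_single_cluster_equals_whole_table_summary(self):
        rng = np.random.default_rng(9)
        t = FeatureTable(
            values=rng.normal(size=(30, 3)),
            row_ids=tuple(f"i{i}" for i in range(30)),
            feature_names=("a", "b", "c"),
        )
        profile = cluster_profiles(t, np.zeros(30, dtype=int))
        for j, name in enumerate(t.feature_names):
            row = profile[profile["feature"] == name].iloc[0]
            assert row["median"] == pytest.approx(np.median(t.values[:, j]))

    def test_medians_match_sort_based_oracle(self):
        rng = np.random.default_rng(10)
        t = FeatureTable(
            values=rng.normal(size=(40, 2)),
            row_ids=tuple(f"i{i}" for i in range(40)),
            feature_names=("a", "b"),
        )
        labels = (np.arange(40) % 2).astype(int)
        profile = cluster_profiles(t, labels)
        for cluster in (0, 1):
            sub = np.sort(t.values[labels == cluster, 0])
            oracle = (sub[len(sub) // 2 - 1] + sub[len(sub) // 2]) / 2
            row = profile[(profile["cluster"] == cluster) & (profile["feature"] == "a")]
            assert row["median"].iloc[0] == pytest.approx(oracle)

    def test_label_coverage_checked(self):
        t = FeatureTable(values=np.ones((4, 1)), row_ids=tuple("abcd"), feature_names=("f",))
        with pytest.raises(ValueError, match="every instance"):
            cluster_profiles(t, np.zeros(3, dtype=int))
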