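import numpy as np
import pandas as pd
import pytest
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score, silhouette_score

from shiftsleep import clustering


def ward_oracle(X):
    """Greedy Ward agglomeration via explicit objective-increase search.

    Returns the merge heights in order, using the same distance scale as
    scipy (d(A,B) = sqrt(2 |A||B| / (|A|+|B|)) * ||cA - cB||).
    """
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                ca, cb = X[a].mean(axis=0), X[b].mean(axis=0)
                na, nb = len(a), len(b)
                d = np.sqrt(2 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


class TestWardCluster:
    def test_recovers_planted_blobs(self):
        X, y = make_blobs(n_samples=120, centers=6, cluster_std=0.4,
                          center_box=(-12, 12), random_state=0)
        model = clustering.ward_cluster(X)
        # a cut between the 6th- and 5th-to-last merges isolates the blobs
        threshold = (model.Z[-6, 2] + model.Z[-5, 2]) / 2
        labels = clustering.cut(model.Z, threshold)
        assert len(np.unique(labels)) == 6
        assert adjusted_rand_score(y, labels) > 0.99
        # the default primary threshold is data-dependent but still groups
        # whole blobs (never splits one)
        df = pd.DataFrame({"truth": y, "cut": model.labels_primary})
        assert (df.groupby("truth")["cut"].nunique() == 1).all()

    def test_duplicate_points_merge_at_zero(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        model = clustering.ward_cluster(X)
        assert model.Z[0, 2] == 0.0

    def test_merge_heights_match_bruteforce_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            X = rng.normal(0, 1, (n, 3))
            model = clustering.ward_cluster(X)
            # greedy sequence can differ on ties; continuous data has none
            np.testing.assert_allclose(
                np.sort(model.Z[:, 2]), np.sort(ward_oracle(X)), rtol=1e-8
            )

    def test_merge_heights_nondecreasing(self, rng):
        X = rng.normal(0, 1, (40, 5))
        model = clustering.ward_cluster(X)
        assert (np.diff(model.Z[:, 2]) >= -1e-12).all()

    def test_default_primary_threshold(self, rng):
        X = rng.normal(0, 1, (30, 4))
        model = clustering.ward_cluster(X)
        assert model.primary_threshold == pytest.approx(0.7 * model.Z[-1, 2])

    def test_nonpositive_threshold_errors(self, rng):
        X = rng.normal(0, 1, (10, 2))
        with pytest.raises(ValueError):
            clustering.ward_cluster(X, primary_threshold=-1.0)
        with pytest.raises(ValueError):
            clustering.cut(clustering.ward_cluster(X).Z, 0.0)

    def test_subclusters_nest_in_primary(self, rng):
        X = rng.normal(0, 1, (60, 4))
        model = clustering.ward_cluster(X, secondary_threshold=1.0)
        df = pd.DataFrame({"p": model.labels_primary, "s": model.labels_secondary})
        assert (df.groupby("s")["p"].nunique() == 1).all()


class TestCut:
    def test_extreme_thresholds(self, rng):
        X = rng.normal(0, 1, (25, 3))
        model = clustering.ward_cluster(X)
        assert len(np.unique(clustering.cut(model.Z, model.Z[-1, 2] + 1))) == 1
        assert len(np.unique(clustering.cut(model.Z, 1e-12))) == 25

    def test_count_monotone_in_threshold(self, rng):
        X = rng.normal(0, 1, (30, 3))
        model = clustering.ward_cluster(X)
        counts = [
            len(np.unique(clustering.cut(model.Z, t)))
            for t in np.linspace(0.01, model.Z[-1, 2] + 0.1, 25)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSelectFeatures:
    def test_wellbeing_absent(self, small_daily):
        X, names, idx = clustering.select_cluster_features(small_daily)
        from shiftsleep.features import SLEEP_QUALITY_FEATURES, WELLBEING_FEATURES

        assert not set(names) & set(WELLBEING_FEATURES)
        assert not set(names) & set(SLEEP_QUALITY_FEATURES)
        assert "sri_7" not in names and "caffeine_to_sleep" not in names

    def test_standardized(self, small_daily):
        X, _, _ = clustering.select_cluster_features(small_daily)
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(X.std(axis=0), 1, atol=1e-9)

    def test_all_complete_toy_keeps_rows(self):
        from shiftsleep.features import CLUSTER_FEATURES

        rng = np.random.default_rng(0)
        daily = pd.DataFrame(rng.normal(0, 1, (20, len(CLUSTER_FEATURES))),
                             columns=CLUSTER_FEATURES)
        daily.insert(0, "participant", "P1")
        daily.insert(1, "date", pd.date_range("2021-03-01", periods=20).date)
        X, names, idx = clustering.select_cluster_features(daily)
        assert X.shape[0] == 20

    def test_retained_fraction_near_complete_rate(self, small_daily):
        X, _, _ = clustering.select_cluster_features(small_daily)
        frac = X.shape[0] / len(small_daily)
        # small cohort uses 5%/5%/3% dropout; work-history lags amplify it
        assert 0.6 < frac < 0.95


class TestEmbed:
    def test_pca_component_bookkeeping(self, rng):
        # eigenvalue oracle: data with known variance split
        X = rng.normal(0, 1, (200, 10)) * np.array([10, 8, 6, 1, 1, 1, 1, 1, 1, 1])
        X = X - X.mean(axis=0)
        cov_eigs = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        cum = np.cumsum(cov_eigs) / cov_eigs.sum()
        expect = int(np.searchsorted(cum, 0.95) + 1)
        assert clustering.n_components_for_variance(X, 0.95) == expect

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(0, 1, (80, 6))
        c1 = clustering.embed(X, seed=4, perplexity=10)
        c2 = clustering.embed(X, seed=4, perplexity=10)
        np.testing.assert_array_equal(c1, c2)

    def test_blobs_keep_silhouette(self):
        X, y = make_blobs(n_samples=150, centers=4, cluster_std=0.5, random_state=1)
        coords = clustering.embed(X, seed=0, perplexity=20)
        assert silhouette_score(coords, y) > 0.5

    def test_too_small_for_perplexity(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            clustering.embed(rng.normal(0, 1, (10, 3)), perplexity=30)


class TestProfile:
    def test_single_cluster_equals_global_means(self, small_daily):
        X, names, idx = clustering.select_cluster_features(small_daily)
        model = clustering.ward_cluster(
            X, names, idx, primary_threshold=1e9, secondary_threshold=1e9
        )
        prof = clustering.profile(model, small_daily)
        assert len(prof) == 1
        merged = idx.merge(small_daily, on=["participant", "date"])
        assert prof.iloc[0]["sleep_duration"] == pytest.approx(
            merged["sleep_duration"].mean()
        )

    def test_matches_groupby_oracle(self, small_daily):
        X, names, idx = clustering.select_cluster_features(small_daily)
        model = clustering.ward_cluster(X, names, idx)
        prof = clustering.profile(model, small_daily)
        merged = idx.copy()
        merged["cluster"] = model.labels_primary
        merged = merged.merge(small_daily, on=["participant", "date"])
        oracle = merged.groupby("cluster")["steps"].mean()
        pd.testing.assert_series_equal(prof["steps"], oracle, check_names=False)

    def test_includes_wellbeing_and_flags(self, small_daily):
        X, names, idx = clustering.select_cluster_features(small_daily)
        model = clustering.ward_cluster(X, names, idx)
        prof = clustering.profile(model, small_daily)
        assert "happiness_morn" in prof.columns
        assert prof["flag_shortest_sleep"].sum() == 1
        assert prof["flag_most_steps"].sum() == 1


class TestShortSleepCluster:
    def test_day_to_midnight_days_form_short_sleep_cluster(self, small_daily):
        """Days following the day->midnight shift context have ~220-min sleep;
        the shortest-sleep cluster mean should sit well below the population
        mean."""
        X, names, idx = clustering.select_cluster_features(small_daily)
        model = clustering.ward_cluster(X, names, idx)
        # quick-return days are a small minority at this cohort size, so the
        # merge tree only isolates them at finer cuts; some cut must expose a
        # cluster of them with far-below-average sleep
        overall = small_daily["sleep_duration"].mean()
        shortest = np.inf
        for k in range(4, 31):
            threshold = (model.Z[-k, 2] + model.Z[-k + 1, 2]) / 2
            merged = idx.copy()
            merged["cluster"] = clustering.cut(model.Z, threshold)
            merged = merged.merge(small_daily, on=["participant", "date"])
            by_cluster = merged.groupby("cluster")["sleep_duration"].agg(["mean", "size"])
            by_cluster = by_cluster[by_cluster["size"] >= 5]
            shortest = min(shortest, by_cluster["mean"].min())
        assert shortest < 310  # quick-return regime sits near 220-300 min
        assert shortest < overall - 100
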