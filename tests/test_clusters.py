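"""Correlation-distance construction, k-means niches, elbow, profiles, trends."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import adjusted_rand_score

from taunich.clusters import (
    NicheKMeans,
    correlation_distance,
    elbow_select,
    kmeans_niches,
    niche_profiles,
    niche_trend,
    wss_curve,
)


class TestCorrelationDistance:
    def test_self_distance_zero(self):
        p = np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        d = correlation_distance(p).matrix.to_numpy()
        assert d[0, 0] == 0.0 and d[1, 1] == 0.0

    def test_uncorrelated_pair_distance_one(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])  # r = 0
        d = correlation_distance(np.vstack([a, b])).matrix.to_numpy()
        assert d[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_pair_distance_zero_under_r_squared(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        d2 = correlation_distance(np.vstack([a, -a])).matrix.to_numpy()
        assert d2[0, 1] == pytest.approx(0.0, abs=1e-12)
        d1 = correlation_distance(np.vstack([a, -a]), metric="1-r").matrix
        assert d1.to_numpy()[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(8)
        profiles = rng.uniform(size=(40, 15))
        d = correlation_distance(profiles).matrix.to_numpy()
        for i in range(0, 40, 7):
            for j in range(i + 1, 40, 5):
                r = pearsonr(profiles[i], profiles[j]).statistic
                assert d[i, j] == pytest.approx(1 - r**2, abs=1e-12)

    def test_constant_profiles_dropped_then_error(self):
        flat = np.ones((3, 5))
        with pytest.raises(ValueError):
            correlation_distance(flat)
        mixed = np.vstack([np.ones(5), [1, 2, 3, 4, 5], [5, 4, 3, 2, 1]])
        cd = correlation_distance(mixed)
        assert cd.dropped_taxa == ["t0"]
        assert cd.matrix.shape == (2, 2)


def _planted_profiles(n_per=8, n_sites=12, seed=0):
    rng = np.random.default_rng(seed)
    up = np.linspace(0.1, 1.0, n_sites)
    down = up[::-1]
    rows, truth = [], []
    for g, base in enumerate([up, down]):
        for _ in range(n_per):
            rows.append(base + rng.normal(0, 0.02, n_sites))
            truth.append(g)
    return np.array(rows), np.array(truth)


class TestKMeans:
    def test_planted_partition_recovered(self):
        # increasing vs decreasing profiles are perfectly *anti*correlated,
        # which the 1-r^2 convention deliberately treats as similar; the
        # signed 1-r metric separates them perfectly
        profiles, truth = _planted_profiles()
        d = correlation_distance(profiles, metric="1-r")
        labels, _ = kmeans_niches(d, k=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_planted_partition_recovered_under_r_squared(self):
        # under 1-r^2 the groups must be uncorrelated, not anticorrelated
        rng = np.random.default_rng(1)
        n_sites = 12
        up = np.linspace(0.1, 1.0, n_sites)
        hump = np.exp(-0.5 * ((np.arange(n_sites) - 5.5) / 2.0) ** 2)
        rows = [up + rng.normal(0, 0.02, n_sites) for _ in range(8)]
        rows += [hump + rng.normal(0, 0.02, n_sites) for _ in range(8)]
        truth = np.repeat([0, 1], 8)
        d = correlation_distance(np.array(rows))
        labels, _ = kmeans_niches(d, k=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_zero_wss(self):
        profiles, _ = _planted_profiles(n_per=3)
        d = correlation_distance(profiles)
        _, wss = kmeans_niches(d, k=6, seed=0)
        assert wss == pytest.approx(0.0, abs=1e-9)

    def test_wss_non_increasing_in_k(self):
        profiles, _ = _planted_profiles(n_per=10, seed=3)
        d = correlation_distance(profiles)
        curve = wss_curve(d, range(1, 9), seed=0)
        vals = [curve[k] for k in sorted(curve)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_invalid_k(self):
        profiles, _ = _planted_profiles(n_per=2)
        d = correlation_distance(profiles)
        with pytest.raises(ValueError):
            kmeans_niches(d, k=0)


class TestElbow:
    def test_second_difference_example(self):
        assert elbow_select({1: 100.0, 2: 20.0, 3: 18.0, 4: 17.0}) == 2

    def test_weak_elbow_warns_but_returns(self):
        linear = {k: 100.0 - 10 * k for k in range(1, 8)}
        with pytest.warns(UserWarning, match="weak elbow"):
            k = elbow_select(linear)
        assert k in linear

    def test_requires_three_consecutive(self):
        with pytest.raises(ValueError):
            elbow_select({1: 5.0, 2: 3.0})
        with pytest.raises(ValueError):
            elbow_select({1: 5.0, 3: 3.0, 5: 2.0})


class TestNicheProfiles:
    def test_single_cluster_conserves_everything(self, toy_counts):
        labels = pd.Series(0, index=toy_counts.index)
        na = niche_profiles(toy_counts, labels)
        assert np.allclose(na.niche_profile.loc[0], 1.0)
        assert na.niche_share.loc[0] == pytest.approx(1.0)

    def test_additivity_over_clusters(self, toy_counts):
        labels = pd.Series([0, 1, 0, 1], index=toy_counts.index)
        na = niche_profiles(toy_counts, labels)
        total = na.niche_profile.sum(axis=0)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_partial_coverage_leaves_remainder(self, toy_counts):
        labels = pd.Series([0, 0], index=["left", "right"])
        na = niche_profiles(toy_counts, labels)
        covered = toy_counts.loc[["left", "right"]].sum() / toy_counts.sum()
        assert np.allclose(na.niche_profile.loc[0], covered)


class TestOnSyntheticGradient:
    def test_structured_guilds_recovered_at_k3(self, default_gradient):
        res = default_gradient
        truth = res.guild_truth
        est = NicheKMeans(k=3, random_state=0).fit(res.community)
        structured = truth[truth != "noise"]
        common = est.labels_.index.intersection(structured.index)
        ari = adjusted_rand_score(structured[common], est.labels_[common])
        assert ari >= 0.9

    def test_elbow_sees_the_planted_structure(self, default_gradient):
        est = NicheKMeans(k="auto", random_state=0).fit(
            default_gradient.community
        )
        assert est.k_ in {3, 4, 5}

    def test_short_tau_niche_profile_declines(self, default_gradient):
        res = default_gradient
        truth = res.guild_truth
        labels = truth[truth != "noise"]
        na = niche_profiles(res.community.counts, labels)
        tau = res.community.tau.to_numpy()
        rho = spearmanr(na.niche_profile.loc["short_tau"], tau).statistic
        assert rho < 0

    def test_mass_conservation_with_unclustered_share(self, default_gradient):
        res = default_gradient
        est = NicheKMeans(k=3, random_state=0).fit(res.community)
        clustered = est.assignment_.niche_profile.sum(axis=0)
        counts = res.community.counts
        unclustered = (
            counts.drop(index=est.kept_taxa_).sum() / counts.sum()
        )
        assert np.allclose(clustered + unclustered, 1.0, atol=1e-9)

    def test_embedded_variant_agrees_on_clear_structure(self, default_gradient):
        res = default_gradient
        a = NicheKMeans(k=3, random_state=0).fit(res.community).labels_
        b = NicheKMeans(k=3, random_state=0, embed=True).fit(res.community).labels_
        assert adjusted_rand_score(a, b.loc[a.index]) >= 0.8


class TestNicheTrend:
    def test_constant_profile_flat_fit(self):
        tau = np.geomspace(1, 1e6, 20)
        fit = niche_trend(np.full(20, 0.3), tau)
        assert np.allclose(fit.fitted, 0.3)
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_monotone_curve_explained(self):
        tau = np.geomspace(1, 1e6, 30)
        y = 1 / (1 + np.exp(-(np.log10(tau) - 3)))
        fit = niche_trend(y, tau)
        assert fit.deviance_explained >= 0.99

    def test_fitted_values_stay_in_data_range(self):
        rng = np.random.default_rng(0)
        tau = np.geomspace(1, 1e6, 25)
        y = np.clip(rng.uniform(0.1, 0.9, 25), 0, 1)
        fit = niche_trend(y, tau)
        margin = 0.5 * (y.max() - y.min())
        assert fit.fitted.min() >= y.min() - margin
        assert fit.fitted.max() <= y.max() + margin

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            niche_trend(np.ones(5), np.geomspace(1, 10, 5))
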