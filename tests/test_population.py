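"""Species-level statistics: weighted moments, consistency, normality,
mixtures, and the song-tag comparison."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

import fractalvoc as fv
from fractalvoc.errors import DomainError, UsageError
from fractalvoc.population import (
    MeasurementSet,
    MixtureModel,
    consistency_statistic,
    fit_mixture,
    ks_normality,
    mixture_pdf,
    species_summary,
    tag_comparison,
    weighted_stats,
)


class TestWeightedStats:
    def test_equal_sigmas_reduce_to_plain_mean(self):
        x = np.array([0.2, 0.8, 1.1, 1.5])
        ms = MeasurementSet(x, np.full(4, 0.3))
        st_ = weighted_stats(ms)
        assert st_.mu == pytest.approx(x.mean(), abs=1e-12)
        assert st_.sigma_mu == pytest.approx(0.3 / 2.0, abs=1e-12)

    def test_two_point_example_exact(self):
        ms = MeasurementSet([1.0, 2.0], [1.0, 0.5])
        st_ = weighted_stats(ms)
        assert st_.mu == pytest.approx(1.8, abs=1e-12)
        assert st_.sigma_mu == pytest.approx(5 ** -0.5, abs=1e-12)
        assert st_.sigma_pop == pytest.approx(0.16, abs=1e-12)

    def test_single_measurement(self):
        st_ = weighted_stats(MeasurementSet([1.3], [0.2]))
        assert st_.mu == pytest.approx(1.3, abs=1e-12)
        assert st_.sigma_mu == pytest.approx(0.2)
        assert st_.sigma_pop == pytest.approx(0.0, abs=1e-24)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(DomainError):
            MeasurementSet([1.0], [0.0])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=4.0),
                st.floats(min_value=0.01, max_value=2.0),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_weighted_mean_bounds(self, pairs):
        x = np.array([p[0] for p in pairs])
        s = np.array([p[1] for p in pairs])
        st_ = weighted_stats(MeasurementSet(x, s))
        assert x.min() - 1e-9 <= st_.mu <= x.max() + 1e-9
        assert st_.sigma_mu <= s.min() + 1e-9


class TestConsistencyStatistic:
    def test_zero_residuals(self):
        ms = MeasurementSet([1.0, 1.0, 1.0], [0.5, 0.5, 0.5])
        assert consistency_statistic(ms, 1.0, 0.5 / np.sqrt(3)) == 0.0

    def test_two_point_example_exact(self):
        ms = MeasurementSet([0.0, 2.0], [1.0, 1.0])
        val = consistency_statistic(ms, 1.0, 1 / np.sqrt(2))
        assert val == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_single_measurement_rejected(self):
        with pytest.raises(DomainError):
            consistency_statistic(MeasurementSet([1.0], [1.0]), 1.0, 1.0)

    def test_consistent_population_near_one(self):
        rng = np.random.default_rng(10)
        sig = np.ones(1000)
        x = rng.normal(1.0, sig)
        ms = MeasurementSet(x, sig)
        st_ = weighted_stats(ms)
        val = consistency_statistic(ms, st_.mu, st_.sigma_mu)
        assert 0.85 <= val <= 1.15

    def test_monte_carlo_mean_calibrated(self):
        # over many consistent replicates the statistic averages to ~1
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(200):
            sig = rng.uniform(0.5, 1.5, 50)
            x = rng.normal(0.7, sig)
            ms = MeasurementSet(x, sig)
            st_ = weighted_stats(ms)
            vals.append(consistency_statistic(ms, st_.mu, st_.sigma_mu))
        assert abs(np.mean(vals) - 1.0) < 0.05

    def test_inflated_scatter_blows_up(self):
        rng = np.random.default_rng(11)
        sig = np.full(200, 0.1)
        x = rng.normal(1.0, 10 * sig)
        ms = MeasurementSet(x, sig)
        st_ = weighted_stats(ms)
        assert consistency_statistic(ms, st_.mu, st_.sigma_mu) > 10


class TestKsNormality:
    def test_quantile_placed_sample(self):
        m = 20
        qs = (np.arange(m) + 0.5) / m
        x = sstats.norm.ppf(qs, 1.0, 0.5)
        ms = MeasurementSet(x, np.ones(m))
        d, p = ks_normality(ms, 1.0, 0.5)
        assert d <= 1.0 / m + 1e-12

    def test_matches_bruteforce_cdf_gap(self):
        x = np.array([-1.2, -0.3, 0.1, 0.8, 2.0])
        ms = MeasurementSet(x, np.ones(5))
        d, p = ks_normality(ms, 0.0, 1.0)
        xs = np.sort(x)
        cdf = sstats.norm.cdf(xs)
        n = len(xs)
        gaps = np.maximum(np.arange(1, n + 1) / n - cdf, cdf - np.arange(n) / n)
        assert d == pytest.approx(gaps.max(), abs=1e-12)

    def test_bimodal_sample_rejected_in_majority_of_seeds(self):
        rejections = 0
        n_seeds = 9
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            comp = rng.integers(0, 2, 30)
            x = np.where(comp == 0, rng.normal(0.5, 0.1, 30), rng.normal(2.5, 0.1, 30))
            ms = MeasurementSet(x, np.ones(30))
            mu, sd = x.mean(), x.std()
            _, p = ks_normality(ms, mu, sd)
            rejections += p < 0.05
        assert rejections > n_seeds / 2

    def test_invalid_sigma(self):
        ms = MeasurementSet([0.1, 0.2, 0.3], [1, 1, 1])
        with pytest.raises(DomainError):
            ks_normality(ms, 0.0, 0.0)


class TestMixturePdf:
    def test_single_mode_reduces_to_normal(self):
        model = MixtureModel(1, [2.0], [1.0], [0.3])
        grid = np.linspace(-1, 3, 7)
        np.testing.assert_allclose(
            mixture_pdf(grid, model), sstats.norm.pdf(grid, 1.0, 0.3), rtol=1e-12
        )

    def test_normalized(self):
        model = MixtureModel(3, [1.0, 5.0, 2.0], [0.5, 1.5, 3.0], [0.2, 0.4, 0.1])
        grid = np.linspace(-10, 15, 20001)
        total = np.trapezoid(mixture_pdf(grid, model), grid)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_two_mode_point_value(self):
        model = MixtureModel(2, [1.0, 1.0], [0.0, 2.0], [1.0, 1.0])
        val = mixture_pdf(1.0, model)
        assert val == pytest.approx(sstats.norm.pdf(1.0, 0.0, 1.0), rel=1e-9)

    def test_ordering_enforced(self):
        with pytest.raises(DomainError):
            MixtureModel(2, [1.0, 1.0], [2.0, 1.0], [0.5, 0.5])


class TestFitMixture:
    def test_unimodal_recovery(self):
        model = MixtureModel(1, [1.0], [1.0], [0.2])
        ms = fv.gen_beta_population(model, 30, 0.05, seed=1)
        fit = fit_mixture(ms, 1, nlive=150, seed=2)
        sigma_mu = ms.values.std() / np.sqrt(len(ms))
        assert abs(fit.means[0] - 1.0) < 3 * sigma_mu + 0.05
        assert np.isfinite(fit.logz)

    def test_bimodal_recovery_and_ordering(self):
        model = MixtureModel(2, [1.0, 1.0], [0.5, 2.5], [0.1, 0.1])
        ms = fv.gen_beta_population(model, 30, 0.05, seed=3)
        fit = fit_mixture(ms, 2, nlive=200, seed=4)
        assert np.all(np.diff(fit.means) > 0)
        assert abs(fit.means[0] - 0.5) < 0.1
        assert abs(fit.means[1] - 2.5) < 0.1

    def test_unimodal_occam_preference(self):
        # evidence should favour one mode over two on unimodal data
        model = MixtureModel(1, [1.0], [1.0], [0.2])
        wins = 0
        reps = 5
        for rep in range(reps):
            ms = fv.gen_beta_population(model, 30, 0.05, seed=50 + rep)
            z1 = fit_mixture(ms, 1, nlive=150, seed=rep).logz
            z2 = fit_mixture(ms, 2, nlive=150, seed=100 + rep).logz
            wins += z1 > z2
        assert wins >= 4

    def test_invalid_mode_count(self):
        ms = MeasurementSet(np.linspace(0.5, 1.5, 10), np.full(10, 0.1))
        with pytest.raises(DomainError):
            fit_mixture(ms, 6)


class TestSpeciesSummary:
    def test_fields_populated(self):
        rng = np.random.default_rng(5)
        ms = MeasurementSet(rng.normal(1.0, 0.3, 12), np.full(12, 0.05))
        st_ = species_summary(ms)
        assert st_.sigma_pop > 0
        assert np.isfinite(st_.consistency)
        assert 0 <= st_.ks_p <= 1
        assert st_.pop_std == pytest.approx(np.sqrt(st_.sigma_pop))

    def test_single_recording_degenerate(self):
        st_ = species_summary(MeasurementSet([0.9], [0.1]))
        assert st_.sigma_pop == 0.0
        assert np.isnan(st_.consistency)
        assert np.isnan(st_.ks_p)


class TestTagComparison:
    def _stats(self, mu, tag, species):
        return fv.SpeciesStats(
            mu=mu, sigma_mu=0.05, sigma_pop=0.04, species=species, tag=tag
        )

    def test_identical_groups_zero_difference(self):
        stats = [
            self._stats(1.0, "musical", "a"),
            self._stats(1.0, "non-musical", "b"),
        ]
        out = tag_comparison(stats)
        assert out["difference"] == pytest.approx(0.0)

    def test_constructed_difference(self):
        stats = [
            self._stats(1.2, "musical", "a"),
            self._stats(0.8, "non-musical", "b"),
        ]
        assert tag_comparison(stats)["difference"] == pytest.approx(0.4)

    def test_curve_count_matches_species_count(self):
        stats = [
            self._stats(1.2, "musical", "a"),
            self._stats(1.0, "musical", "b"),
            self._stats(0.8, "non-musical", "c"),
        ]
        out = tag_comparison(stats)
        assert len(out["curves"]["musical"]) + len(out["curves"]["non-musical"]) == 3

    def test_empty_group_rejected(self):
        with pytest.raises(UsageError):
            tag_comparison([self._stats(1.0, "musical", "a")])
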