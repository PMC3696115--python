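"""Group-level t→z inference, two-sample comparisons, and PMA trends."""

import numpy as np
import pytest
from scipy import stats

from nirsconn.inference import (
    GroupComparison,
    InferenceConfig,
    OneSampleZMap,
    PMATrend,
    t_to_z,
    two_sample_t,
    z_threshold_for_p,
)

from test_artifacts import FULLTERM_COUNTS, PRETERM_COUNTS


def _expand(counts):
    return np.concatenate([[k] * v for k, v in counts.items()]).astype(float)


class TestTtoZ:
    def test_zero_stays_zero(self):
        assert t_to_z(0.0, 23) == 0.0

    def test_closed_form_value(self):
        assert t_to_z(3.0, 23) == pytest.approx(3.0 / np.sqrt(23 / 21), abs=1e-3)
        assert t_to_z(3.0, 23) == pytest.approx(2.8667, abs=1e-3)

    def test_large_df_limit_is_identity(self):
        assert t_to_z(1.7, 10**6) == pytest.approx(1.7, abs=1e-5)

    def test_low_df_rejected(self):
        with pytest.raises(ValueError, match="df > 2"):
            t_to_z(1.0, 2)

    def test_strictly_monotone_in_t(self):
        ts = np.linspace(-4, 4, 101)
        zs = t_to_z(ts, 10)
        assert np.all(np.diff(zs) > 0)

    def test_null_variance_standardized(self, rng):
        # converted z of a null t sample has unit variance
        t = rng.standard_t(df=10, size=200_000)
        assert np.std(t_to_z(t, 10)) == pytest.approx(1.0, abs=0.01)


class TestThreshold:
    def test_half_maps_to_zero(self):
        assert z_threshold_for_p(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_common_quantiles(self):
        assert round(z_threshold_for_p(0.0005), 2) == 3.29
        assert round(z_threshold_for_p(0.025), 2) == 1.96

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            z_threshold_for_p(0.0)


class TestTwoSampleT:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        t, df, p = two_sample_t(x, x)
        assert t == 0.0 and df == 4

    def test_artifact_count_comparison_reproduces_reported_t(self):
        # full-term minus preterm ordering on the reported distributions
        t, df, p = two_sample_t(_expand(FULLTERM_COUNTS), _expand(PRETERM_COUNTS))
        assert round(t, 2) == -0.11
        assert round(p, 2) == 0.91
        assert df == 47

    def test_hand_computed_pooled_t_on_toy(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        t, df, _ = two_sample_t(a, b)
        assert t == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestOneSampleMap:
    def test_degenerate_identical_values_masked(self, rng):
        Z = np.hstack([np.zeros((10, 1)), rng.normal(size=(10, 3))])
        fitted = OneSampleZMap().fit(Z)
        assert np.isnan(fitted.t_[0]) and np.isnan(fitted.z_[0])
        assert np.all(np.isfinite(fitted.z_[1:]))

    def test_matches_explicit_mean_sd_formula(self, rng):
        Z = rng.normal(size=(24, 30))
        fitted = OneSampleZMap().fit(Z)
        mean = Z.mean(axis=0)
        sd = Z.std(axis=0, ddof=1)
        oracle_t = mean / (sd / np.sqrt(24))
        np.testing.assert_allclose(fitted.t_, oracle_t, atol=1e-10)
        assert fitted.df_ == 23
        np.testing.assert_allclose(
            fitted.z_, oracle_t / np.sqrt(23 / 21), atol=1e-10
        )

    def test_planted_positive_mean_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Z = rng.normal(loc=np.arctanh(0.5), scale=0.2, size=(24, 5))
            hits += OneSampleZMap().fit(Z).z_[0] > 0
        assert hits >= 19

    def test_null_z_distribution_standard_normal_ks(self):
        # pooled over pairs and seeds, the converted one-sample z is close
        # enough to N(0,1) that a KS check at alpha = 0.01 passes
        ks = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            Z = rng.normal(size=(24, 400))
            fitted = OneSampleZMap().fit(Z)
            ks.append(stats.kstest(fitted.z_, "norm").statistic)
        critical = stats.ksone.ppf(1 - 0.01 / 2, 400)
        assert np.mean(ks) < critical


class TestGroupComparison:
    def test_identical_groups_give_zero_z(self, rng):
        Z = rng.normal(size=(10, 20))
        fitted = GroupComparison().fit(Z, Z.copy())
        np.testing.assert_allclose(fitted.z_, 0.0, atol=1e-12)
        assert not fitted.significant_.any()

    def test_direction_matches_mean_difference_sign(self, rng):
        Za = rng.normal(size=(15, 40))
        Zb = rng.normal(size=(12, 40))
        fitted = GroupComparison().fit(Za, Zb)
        diff = Za.mean(axis=0) - Zb.mean(axis=0)
        for k in np.flatnonzero(fitted.significant_):
            assert (fitted.direction_[k] == "a_higher") == (diff[k] > 0)
        # direction defined for all pairs
        assert set(fitted.direction_) <= {"a_higher", "b_higher"}

    def test_pooled_t_matches_scipy(self, rng):
        Za = rng.normal(size=(25, 10))
        Zb = rng.normal(size=(24, 10))
        fitted = GroupComparison().fit(Za, Zb)
        oracle = stats.ttest_ind(Za, Zb, axis=0)
        np.testing.assert_allclose(fitted.t_, oracle.statistic, atol=1e-10)
        assert np.all(fitted.df_ == 47)

    def test_welch_option(self, rng):
        Za = rng.normal(scale=3.0, size=(25, 10))
        Zb = rng.normal(size=(24, 10))
        cfg = InferenceConfig(two_sample_variance="welch")
        fitted = GroupComparison(config=cfg).fit(Za, Zb)
        oracle = stats.ttest_ind(Za, Zb, axis=0, equal_var=False)
        np.testing.assert_allclose(fitted.t_, oracle.statistic, atol=1e-10)

    def test_moment_converted_null_tail_matches_scaled_t(self, rng):
        # the t -> z conversion standardizes variance, not shape: the exact
        # null exceedance beyond |z| > 3.29 is the scaled-t tail, ~1.5e-3
        # at df = 47 (not the normal 1.0e-3)
        n = 2_000_000
        t = rng.standard_t(df=47, size=n)
        z = t_to_z(t, 47)
        frac = np.mean(np.abs(z) > 3.29)
        expected = 2 * stats.t.sf(3.29 * np.sqrt(47 / 45), df=47)
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected / n))
        assert expected == pytest.approx(1.54e-3, abs=2e-5)


class TestPMATrend:
    def test_perfect_linear_trend_gives_unit_correlation(self):
        pma = np.linspace(37, 42, 12)
        Z = np.outer(2.0 + 0.1 * pma, np.ones(3))
        fitted = PMATrend().fit(Z, pma)
        np.testing.assert_allclose(fitted.r_, 1.0, atol=1e-12)
        assert fitted.significant_.all()

    def test_matches_scipy_pearsonr(self, rng):
        pma = rng.uniform(37, 42, size=20)
        Z = rng.normal(size=(20, 6))
        fitted = PMATrend().fit(Z, pma)
        for k in range(6):
            r, p = stats.pearsonr(pma, Z[:, k])
            assert fitted.r_[k] == pytest.approx(r, abs=1e-12)
            assert fitted.p_[k] == pytest.approx(p, abs=1e-12)

    def test_constant_column_masked(self, rng):
        Z = np.hstack([np.full((10, 1), 2.0), rng.normal(size=(10, 2))])
        fitted = PMATrend().fit(Z, np.linspace(37, 42, 10))
        assert np.isnan(fitted.r_[0]) and not fitted.significant_[0]

    def test_preconditions(self, rng):
        Z = rng.normal(size=(4, 3))
        with pytest.raises(ValueError, match="at least 5"):
            PMATrend().fit(Z, np.arange(4.0))
        Z = rng.normal(size=(6, 3))
        with pytest.raises(ValueError, match="all equal"):
            PMATrend().fit(Z, np.full(6, 39.0))


def test_config_validation():
    with pytest.raises(ValueError):
        InferenceConfig(group_z_threshold=-1)
    with pytest.raises(ValueError):
        InferenceConfig(two_sample_variance="other")
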