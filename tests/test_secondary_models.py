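import numpy as np
import pytest
from scipy import stats

from caprokin import (
    ContractError,
    EstimationError,
    FitConfig,
    RatePoint,
    fit_inhibition,
    fit_monod,
    linear_inhibition_mu,
    monod_mu,
    normalize_rates,
    screen_inhibition_significance,
    welch_test,
)


def rate_points(xs, mus, no_growth=()):
    return [
        RatePoint(x=float(x), mu=float(m), replicate_id=f"r{i}",
                  no_growth=bool(x in no_growth))
        for i, (x, m) in enumerate(zip(xs, mus))
    ]


class TestMonod:
    def test_half_saturation_identity(self):
        assert monod_mu(0.35, 0.06, 0.35) == pytest.approx(0.03)

    def test_zero_substrate(self):
        assert monod_mu(0.0, 0.06, 0.35) == 0.0

    def test_direct_evaluation(self):
        assert monod_mu(6.0, 0.06, 0.35) == pytest.approx(0.056693, abs=1e-6)

    def test_invalid_ks(self):
        with pytest.raises(ContractError):
            monod_mu(1.0, 0.06, 0.0)

    def test_increasing_and_saturating(self):
        s = np.linspace(0, 50, 200)
        mu = monod_mu(s, 0.06, 0.35)
        assert np.all(np.diff(mu) > 0)
        assert mu[-1] < 0.06

    def test_noiseless_recovery(self, no_boot_config):
        S = [0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0]
        pts = rate_points(S, [monod_mu(s, 0.06, 0.35) for s in S])
        fit = fit_monod(pts, no_boot_config)
        assert fit.mu_max == pytest.approx(0.06, abs=1e-6)
        assert fit.K_S == pytest.approx(0.35, abs=1e-6)

    def test_flat_rates_collapse_flagged(self, no_boot_config):
        S = [0.1, 0.5, 1.0, 2.0, 4.0]
        fit = fit_monod(rate_points(S, [0.05] * 5), no_boot_config)
        assert fit.ks_at_bound

    def test_single_concentration_rejected(self, no_boot_config):
        with pytest.raises(EstimationError):
            fit_monod(rate_points([1.0] * 4, [0.05] * 4), no_boot_config)

    def test_bootstrap_uncertainty(self, fast_config):
        rng = np.random.default_rng(8)
        S = np.repeat([0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0], 4)
        mu = monod_mu(S, 0.06, 0.35) * (1 + rng.normal(0, 0.05, S.size))
        fit = fit_monod(rate_points(S, mu), fast_config)
        assert fit.uncertainty is not None
        assert fit.uncertainty.sd[1] > 0


class TestNormalizeRates:
    def test_direct_ratio(self):
        pts = rate_points([0, 0, 0, 0, 6], [0.05, 0.05, 0.05, 0.05, 0.025])
        normed = normalize_rates(pts, 0.0)
        assert normed.baseline_mean == pytest.approx(0.05)
        assert normed.points[-1].mu == pytest.approx(0.5)

    def test_baseline_maps_to_one(self):
        pts = rate_points([0, 0, 2], [0.04, 0.06, 0.03])
        normed = normalize_rates(pts, 0.0)
        base = [p.mu for p in normed.points if p.x == 0.0]
        assert np.mean(base) == pytest.approx(1.0)

    def test_missing_baseline_errors(self):
        with pytest.raises(ContractError):
            normalize_rates(rate_points([2, 4], [0.05, 0.04]), 0.0)

    def test_idempotent(self):
        pts = rate_points([0, 0, 4, 8], [0.05, 0.05, 0.03, 0.01])
        once = normalize_rates(pts, 0.0)
        twice = normalize_rates(once.points, 0.0)
        for a, b in zip(once.points, twice.points):
            assert b.mu == pytest.approx(a.mu, rel=1e-12)


class TestLinearInhibition:
    def test_no_inhibition(self):
        assert linear_inhibition_mu(100.0, 0.05, 0.0) == 0.05

    def test_threshold_identity(self):
        assert linear_inhibition_mu(13.6, 1.0, 1 / 13.6) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        assert linear_inhibition_mu(6.0, 1.0, 1 / 13.6) == pytest.approx(
            0.5588, abs=1e-4
        )

    def test_clamped_beyond_threshold(self):
        assert linear_inhibition_mu(20.0, 1.0, 1 / 13.6) == 0.0

    def test_nonincreasing_in_p(self):
        p = np.linspace(0, 20, 100)
        mu = linear_inhibition_mu(p, 1.0, 0.08)
        assert np.all(np.diff(mu) <= 0)

    def test_noiseless_extrapolation(self, no_boot_config):
        P = [0, 2, 4, 6, 8, 10, 12]
        pts = rate_points(P, [1 - p / 13.6 for p in P])
        fit = fit_inhibition(pts, no_boot_config)
        assert fit.P_inhib == pytest.approx(13.6, abs=1e-6)
        assert fit.mu_max == pytest.approx(1.0, abs=1e-6)
        # threshold is exactly 1/K at the point estimate
        assert fit.P_inhib == 1.0 / fit.K

    def test_flat_rates_not_reached(self, no_boot_config):
        pts = rate_points([0, 2, 4, 6], [1.0, 1.0, 1.0, 1.0])
        fit = fit_inhibition(pts, no_boot_config)
        assert not fit.reached
        assert fit.P_inhib is None

    def test_no_growth_points_excluded_by_default(self, no_boot_config):
        P = [0, 2, 4, 6, 10]
        pts = rate_points(P, [1 - p / 8.9 if p < 8.9 else 0.0 for p in P],
                          no_growth=(10,))
        fit = fit_inhibition(pts, no_boot_config)
        assert fit.P_inhib == pytest.approx(8.9, abs=1e-6)
        assert fit.n_points == 4

    def test_mM_conversion_attached(self, fast_config):
        rng = np.random.default_rng(5)
        P = np.repeat([0, 2, 4, 6, 8, 10, 12], 4)
        mu = (1 - P / 13.6) * (1 + rng.normal(0, 0.05, P.size))
        fit = fit_inhibition(rate_points(P, np.clip(mu, 0, None)), fast_config)
        assert fit.P_inhib_mM == pytest.approx(
            fit.P_inhib * 1000.0 / 116.16, rel=1e-9
        )
        assert fit.P_inhib_summary is not None
        assert fit.P_inhib_summary.sd > 0


class TestWelch:
    def test_identical_groups(self):
        r = welch_test([0.05, 0.05, 0.05], [0.05, 0.05, 0.05])
        assert r.t == 0.0
        assert r.p == 1.0
        assert not r.significant

    def test_separated_groups_significant(self):
        r = welch_test([0.050, 0.052, 0.048], [0.040, 0.041, 0.042])
        assert r.p < 0.05
        assert r.significant

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.05, 0.004, 5)
        b = rng.normal(0.045, 0.008, 7)
        ours = welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)
        assert ours.df == pytest.approx(ref.df, rel=1e-10)

    def test_df_within_satterthwaite_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 8))
            b = rng.normal(0, 2, rng.integers(2, 8))
            r = welch_test(a, b)
            assert min(a.size, b.size) - 1 <= r.df + 1e-9
            assert r.df <= a.size + b.size - 2 + 1e-9

    def test_degenerate_zero_variance(self):
        r = welch_test([1.0, 1.0], [2.0, 2.0])
        assert r.p == 0.0
        assert r.degenerate

    def test_small_group_rejected(self):
        with pytest.raises(ContractError):
            welch_test([1.0], [1.0, 2.0])


class TestSignificanceScreen:
    def test_table_length(self):
        pts = rate_points(
            [0, 0, 0, 2, 2, 2, 4, 4, 4],
            [0.05, 0.051, 0.049, 0.04, 0.041, 0.042, 0.03, 0.031, 0.029],
        )
        table = screen_inhibition_significance(pts, 0.0)
        assert len(table) == 2
        assert list(table["x_g_l"]) == [2.0, 4.0]

    def test_strong_separation_all_significant(self):
        pts = rate_points(
            [0, 0, 0, 2, 2, 2, 4, 4, 4],
            [0.05, 0.051, 0.049, 0.02, 0.021, 0.022, 0.01, 0.011, 0.009],
        )
        table = screen_inhibition_significance(pts, 0.0)
        assert table["significant"].all()

    def test_holm_is_more_conservative(self):
        rng = np.random.default_rng(33)
        xs, mus = [], []
        for lvl in [0, 1, 2, 3, 4, 5]:
            xs.extend([lvl] * 4)
            mus.extend(rng.normal(0.05, 0.005, 4))
        plain = screen_inhibition_significance(rate_points(xs, np.abs(mus)), 0)
        holm = screen_inhibition_significance(
            rate_points(xs, np.abs(mus)), 0, holm=True
        )
        assert holm["significant"].sum() <= plain["significant"].sum()
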