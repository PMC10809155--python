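import numpy as np
import pytest

from caprokin import (
    ContractError,
    PropagationError,
    bootstrap_parameters,
    minimize_rmsd,
    propagate_uncertainty,
    rmsd,
)
from caprokin.estimation import ParamDistribution, default_start_grid


def quadratic(x, params):
    return params[0] * x**2


def line(x, params):
    return params[0] * x + params[1]


class TestRmsd:
    @pytest.mark.parametrize(
        "obs, pred, expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
            ([0.0, 0.0], [3.0, 4.0], np.sqrt(25.0 / 2.0)),
            ([1.0], [4.0], 3.0),
        ],
    )
    def test_closed_forms(self, obs, pred, expected):
        assert rmsd(obs, pred) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            rmsd([1.0, 2.0], [1.0])


class TestMinimizeRmsd:
    def test_quadratic_recovery(self):
        x = np.linspace(0, 3, 20)
        y = 2.0 * x**2
        est = minimize_rmsd(quadratic, x, y, bounds=[(0.0, 10.0)])
        assert est.values[0] == pytest.approx(2.0, abs=1e-6)
        assert est.converged
        assert est.rmsd < 1e-8

    def test_underdetermined_rejected(self):
        with pytest.raises(ContractError):
            minimize_rmsd(line, [1.0], [2.0], bounds=[(0, 1), (0, 1)])

    def test_infinite_bounds_rejected(self):
        with pytest.raises(ContractError):
            minimize_rmsd(quadratic, [1, 2], [1, 4], bounds=[(0, np.inf)])

    def test_never_worse_than_any_start(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 5, 25)
        y = 1.3 * x + 0.4 + rng.normal(0, 0.3, x.size)
        bounds = [(0.0, 5.0), (0.0, 5.0)]
        starts = default_start_grid(bounds, 4)
        est = minimize_rmsd(line, x, y, bounds, starts=starts)
        start_rmsds = [rmsd(y, line(x, s)) for s in starts]
        assert est.rmsd <= min(start_rmsds) + 1e-12

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 5, 30)
        y = 0.8 * x + 1.0 + rng.normal(0, 0.1, x.size)
        e1 = minimize_rmsd(line, x, y, [(0, 10), (0, 10)])
        e2 = minimize_rmsd(line, x, y, [(0, 10), (0, 10)])
        assert np.array_equal(e1.values, e2.values)
        assert e1.rmsd == e2.rmsd


class TestBootstrap:
    def _fit(self, x, y):
        return minimize_rmsd(line, x, y, [(0.0, 10.0), (0.0, 10.0)])

    def test_noiseless_bootstrap_collapses(self):
        x = np.linspace(0, 5, 20)
        y = 2.0 * x + 1.0
        est = self._fit(x, y)
        dist = bootstrap_parameters(
            line, x, y, est, [(0, 10), (0, 10)], n_boot=25, seed=99
        )
        assert np.allclose(dist.sd, 0.0, atol=1e-9)
        assert np.allclose(dist.samples, est.values, atol=1e-9)

    def test_same_seed_is_reproducible(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0, 5, 20)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.2, x.size)
        est = self._fit(x, y)
        d1 = bootstrap_parameters(line, x, y, est, [(0, 10), (0, 10)], 30, seed=5)
        d2 = bootstrap_parameters(line, x, y, est, [(0, 10), (0, 10)], 30, seed=5)
        assert np.array_equal(d1.samples, d2.samples)

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 5, 40)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.3, x.size)
        est = self._fit(x, y)
        dist = bootstrap_parameters(line, x, y, est, [(0, 10), (0, 10)], 200, seed=6)
        assert np.all(dist.ci_low <= dist.mean)
        assert np.all(dist.mean <= dist.ci_high)

    def test_bootstrap_sd_scales_with_noise(self):
        """Doubling the noise roughly doubles the bootstrap parameter sd."""
        x = np.tile(np.linspace(0.5, 5, 10), 4)
        ratios = []
        for rep in range(30):
            rng = np.random.default_rng(1000 + rep)
            sds = []
            for sigma in (0.1, 0.2):
                y = 2.0 * x + 1.0 + rng.normal(0, sigma, x.size)
                est = self._fit(x, y)
                dist = bootstrap_parameters(
                    line, x, y, est, [(0, 10), (0, 10)], 200, seed=rep
                )
                sds.append(dist.sd[0])
            ratios.append(sds[1] / sds[0])
        assert 1.6 <= np.mean(ratios) <= 2.4

    def test_case_resampling_preserves_levels(self):
        x = np.repeat([1.0, 2.0, 4.0], 4)
        rng = np.random.default_rng(2)
        y = 2.0 * x + rng.normal(0, 0.1, x.size)
        est = minimize_rmsd(line, x, y, [(0, 10), (0, 10)])
        dist = bootstrap_parameters(
            line, x, y, est, [(0, 10), (0, 10)], 50, seed=3, scheme="case"
        )
        assert dist.n_boot == 50


class TestPropagate:
    def _degenerate(self, value=2.5):
        samples = np.full((100, 1), value)
        return ParamDistribution(
            names=("theta",), samples=samples, mean=np.array([value]),
            sd=np.array([0.0]), ci_low=np.array([value]),
            ci_high=np.array([value]), seed=0,
        )

    def test_identity_on_degenerate(self):
        s = propagate_uncertainty(self._degenerate(), lambda p: p[0], 500, seed=1)
        assert s.mean == pytest.approx(2.5)
        assert s.sd == 0.0

    def test_linearity_doubles_sd(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(1.0, 0.3, size=(2000, 1))
        dist = ParamDistribution(
            names=("theta",), samples=samples, mean=samples.mean(0),
            sd=samples.std(0, ddof=1), ci_low=np.array([0.0]),
            ci_high=np.array([2.0]), seed=0,
        )
        s1 = propagate_uncertainty(dist, lambda p: p[0], 5000, seed=9)
        s2 = propagate_uncertainty(dist, lambda p: 2.0 * p[0], 5000, seed=9)
        assert s2.sd == pytest.approx(2.0 * s1.sd, rel=1e-12)
        assert s2.mean == pytest.approx(2.0 * s1.mean, rel=1e-12)

    def test_reciprocal_matches_delta_method(self):
        """E[1/K] for K ~ N(0.1, 0.005) is 10.025 to second order."""
        rng = np.random.default_rng(4)
        samples = rng.normal(0.1, 0.005, size=(20000, 1))
        dist = ParamDistribution(
            names=("K",), samples=samples, mean=samples.mean(0),
            sd=samples.std(0, ddof=1), ci_low=np.array([0.0]),
            ci_high=np.array([1.0]), seed=0,
        )
        s = propagate_uncertainty(dist, lambda p: 1.0 / p[0], 100000, seed=17)
        assert s.mean == pytest.approx(10.025, rel=0.01)

    def test_all_nonfinite_raises(self):
        with pytest.raises(PropagationError):
            propagate_uncertainty(
                self._degenerate(), lambda p: np.nan, 100, seed=1
            )
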