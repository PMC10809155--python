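"""Primary growth model: the modified (Zwietering-form) Gompertz equation.

The model describes a normalized growth signal y(t) with three directly
interpretable parameters: the asymptote A (maximum normalized growth), the
maximum specific growth rate mu_m (h^-1, the maximal slope of y when y is the
log-normalized signal), and the lag time lam (h, the intercept of the
maximal-slope tangent with y = 0):

    y(t) = A * exp(-exp((mu_m * e / A) * (lam - t) + 1))
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError, EstimationError
from .estimation import (
    FitConfig,
    ParamDistribution,
    ParamEstimate,
    bootstrap_parameters,
    minimize_rmsd,
)
from .growth_io import NormalizedCurve

#: Default minimum rise of the normalized signal (log mode, ~5% signal
#: increase) below which a curve is classified as no-growth.
GROWTH_THRESHOLD = 0.05

_PARAM_NAMES = ("A", "mu_m", "lam")


def gompertz_curve(t, A: float, mu_m: float, lam: float) -> np.ndarray:
    """Evaluate the modified Gompertz curve.

    Monotone non-decreasing in t, bounded above by A; at t = lam the value is
    A * exp(-e).
    """
    if A <= 0:
        raise ContractError("Gompertz asymptote A must be > 0")
    if mu_m < 0:
        raise ContractError("mu_m must be >= 0")
    t = np.asarray(t, dtype=float)
    inner = (mu_m * np.e / A) * (lam - t) + 1.0
    # exp(700) is finite and exp(-exp(700)) underflows cleanly to 0
    return A * np.exp(-np.exp(np.minimum(inner, 700.0)))


def _gompertz_model(t: np.ndarray, params: np.ndarray) -> np.ndarray:
    A, mu_m, lam = params
    inner = (mu_m * np.e / max(A, 1e-300)) * (lam - t) + 1.0
    return A * np.exp(-np.exp(np.minimum(inner, 700.0)))


@dataclass
class GompertzFit:
    """Fitted growth parameters for one curve.

    ``no_growth`` marks curves whose total signal rise stayed below the
    growth threshold; their parameters are NaN and carry no uncertainty.
    """

    A: float
    mu_m: float
    lam: float
    rmsd: float
    no_growth: bool = False
    converged: bool = True
    uncertainty: ParamDistribution | None = None
    replicate_id: str = ""
    condition_id: str = ""

    @classmethod
    def flagged_no_growth(
        cls, curve: NormalizedCurve | None = None
    ) -> "GompertzFit":
        return cls(
            A=float("nan"),
            mu_m=float("nan"),
            lam=float("nan"),
            rmsd=float("nan"),
            no_growth=True,
            converged=True,
            replicate_id=curve.replicate_id if curve else "",
            condition_id=curve.condition_id if curve else "",
        )


def initial_guesses(times: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Data-driven starting values (A0, mu0, lam0).

    A0 is the observed maximum; mu0 the largest finite-difference slope;
    lam0 the intercept of the maximal-slope tangent with y = 0, clamped to
    be non-negative.
    """
    A0 = float(np.max(y))
    slopes = np.diff(y) / np.diff(times)
    i = int(np.argmax(slopes))
    mu0 = float(max(slopes[i], 1e-6))
    t_mid = 0.5 * (times[i] + times[i + 1])
    y_mid = 0.5 * (y[i] + y[i + 1])
    lam0 = float(max(t_mid - y_mid / mu0, 0.0))
    return A0, mu0, lam0


def _start_grid(A0: float, mu0: float, lam0: float, t_max: float) -> np.ndarray:
    factors = (0.5, 1.0, 1.5)
    starts = []
    for fa in factors:
        for fm in factors:
            for fl in factors:
                starts.append(
                    (A0 * fa, mu0 * fm, min(max(lam0 * fl, 0.0), t_max))
                )
    return np.array(starts, dtype=float)


def fit_gompertz(curve: NormalizedCurve, config: FitConfig | None = None,
                 n_boot: int | None = None,
                 growth_threshold: float = GROWTH_THRESHOLD) -> GompertzFit:
    """Fit the modified Gompertz model to a normalized curve.

    Curves whose maximum normalized signal stays below ``growth_threshold``
    are flagged no-growth and returned without parameters.  Bootstrap
    uncertainty (residual resampling) is attached when ``n_boot`` (default
    from ``config``) is positive; pass ``n_boot=0`` to skip it.
    """
    config = config or FitConfig()
    if n_boot is None:
        n_boot = config.n_boot
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.y, dtype=float)
    if curve.mode == "linear":
        # linear-mode curves start at 1; work on the rise above baseline
        y = y - 1.0
    if y.size < 5:
        raise ContractError("fit_gompertz requires >= 5 points")
    if float(np.max(y)) < growth_threshold:
        return GompertzFit.flagged_no_growth(curve)

    A0, mu0, lam0 = initial_guesses(t, y)
    bounds = [
        (1e-8, 2.0 * A0),
        (1e-8, 10.0 * mu0),
        (0.0, float(t[-1])),
    ]
    starts = _start_grid(A0, mu0, lam0, float(t[-1]))
    est = minimize_rmsd(
        _gompertz_model,
        t,
        y,
        bounds,
        starts=starts,
        names=_PARAM_NAMES,
        max_iterations=config.max_iterations,
        tolerance=config.tolerance,
    )
    if not est.converged:
        raise EstimationError(
            f"Gompertz fit did not converge (rmsd {est.rmsd:g}, "
            f"starts A0={A0:g}, mu0={mu0:g}, lam0={lam0:g})"
        )
    uncertainty = None
    if n_boot and n_boot >= 2:
        uncertainty = bootstrap_parameters(
            _gompertz_model,
            t,
            y,
            est,
            bounds,
            n_boot=n_boot,
            seed=config.seed,
            scheme="residual",
            ci_level=config.ci_level,
            max_iterations=config.max_iterations,
            tolerance=config.tolerance,
        )
    A, mu_m, lam = est.values
    return GompertzFit(
        A=float(A),
        mu_m=float(mu_m),
        lam=float(lam),
        rmsd=est.rmsd,
        no_growth=False,
        converged=est.converged,
        uncertainty=uncertainty,
        replicate_id=curve.replicate_id,
        condition_id=curve.condition_id,
    )


@dataclass
class ConditionRate:
    """Replicate-aggregated growth rate for one condition."""

    mean_mu: float
    sd_mu: float
    n: int
    n_no_growth: int
    no_growth: bool = False


def summarize_condition(fits: Iterable[GompertzFit]) -> ConditionRate:
    """Arithmetic mean and sample sd of replicate mu_m for one condition.

    No-growth replicates are excluded from the statistics but counted; a
    condition where every replicate is no-growth is itself flagged no-growth.
    """
    fits = list(fits)
    if not fits:
        raise ContractError("summarize_condition needs at least one fit")
    growing = [f for f in fits if not f.no_growth]
    n_ng = len(fits) - len(growing)
    if not growing:
        return ConditionRate(
            mean_mu=float("nan"), sd_mu=float("nan"), n=0,
            n_no_growth=n_ng, no_growth=True,
        )
    mus = np.array([f.mu_m for f in growing], dtype=float)
    sd = float(np.std(mus, ddof=1)) if mus.size > 1 else 0.0
    return ConditionRate(
        mean_mu=float(np.mean(mus)),
        sd_mu=sd,
        n=int(mus.size),
        n_no_growth=n_ng,
    )
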