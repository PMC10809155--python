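"""Shared fitting engine.

All model fits in this package (primary Gompertz fits and secondary
Monod/inhibition fits) go through the same machinery:

* an RMSD objective, ``sqrt(mean((yhat - y)**2))``;
* deterministic multi-start bounded local minimization;
* bootstrap resampling for parameter uncertainty (residual resampling for
  time-series fits, case resampling stratified by concentration for rate
  fits);
* Monte-Carlo propagation of derived quantities (e.g. the inhibitory
  concentration 1/K) through the bootstrap parameter cloud.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares as _least_squares

from .errors import ContractError, EstimationError, PropagationError

ModelFn = Callable[[np.ndarray, np.ndarray], np.ndarray]
"""A parametric curve evaluator: model(x, params) -> predictions."""


@dataclass
class FitConfig:
    """Fit configuration block (mirrors the YAML ``fit`` section).

    ``seed`` is mandatory: every bootstrap and Monte-Carlo draw in a run is
    derived from it, so reports are reproducible byte for byte.
    """

    seed: int = 1291007
    n_boot: int = 1000
    n_mc: int = 10000
    ci_level: float = 0.95
    max_iterations: int = 1000
    tolerance: float = 1e-14

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("fit config requires an explicit seed")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class ParamEstimate:
    """Point estimate from a multi-start RMSD minimization."""

    names: tuple[str, ...]
    values: np.ndarray
    rmsd: float
    converged: bool
    n_points: int

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


@dataclass
class ParamDistribution:
    """Bootstrap parameter cloud with per-parameter summaries.

    ``samples`` is (n_boot_successful, n_params); ``n_failed`` counts refits
    that did not converge and were dropped from the summaries.
    """

    names: tuple[str, ...]
    samples: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    seed: int
    n_failed: int = 0

    @property
    def n_boot(self) -> int:
        return self.samples.shape[0]


@dataclass
class DerivedSummary:
    """Monte-Carlo summary of a derived quantity."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_mc: int
    n_dropped: int = 0


def rmsd(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square deviation between observations and predictions."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ContractError(
            f"observed and predicted differ in shape: {obs.shape} vs {pred.shape}"
        )
    if obs.size == 0:
        raise ContractError("rmsd requires at least one point")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def default_start_grid(
    bounds: Sequence[tuple[float, float]], n_per_param: int = 3
) -> np.ndarray:
    """Evenly spaced interior grid over the bounds, 3-5 values per parameter."""
    axes = []
    for lo, hi in bounds:
        pts = np.linspace(lo, hi, n_per_param + 2)[1:-1]
        axes.append(pts)
    return np.array(list(itertools.product(*axes)), dtype=float)


def minimize_rmsd(
    model: ModelFn,
    x: Sequence[float],
    y: Sequence[float],
    bounds: Sequence[tuple[float, float]],
    starts: np.ndarray | None = None,
    names: Sequence[str] | None = None,
    max_iterations: int = 1000,
    tolerance: float = 1e-14,
) -> ParamEstimate:
    """Best-of-multi-start bounded minimization of the RMSD objective.

    Each start is refined with a bounded trust-region least-squares solver
    (same argmin as RMSD); the reported objective is the RMSD at the best
    solution.  Determinism: starts are visited in order and ties in final
    RMSD are broken by the lexicographically smallest parameter vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_params = len(bounds)
    if y.size < n_params:
        raise ContractError(
            f"need at least {n_params} data points for {n_params} parameters, "
            f"got {y.size}"
        )
    for lo, hi in bounds:
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ContractError("bounds must be finite ordered intervals")
    if starts is None:
        starts = default_start_grid(bounds)
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = np.clip(starts, lo, hi)

    def residuals(params: np.ndarray) -> np.ndarray:
        pred = model(x, params)
        res = pred - y
        return np.where(np.isfinite(res), res, 1e150)

    def mse(params: np.ndarray) -> float:
        res = residuals(params)
        return float(np.mean(res**2))

    with np.errstate(over="ignore", invalid="ignore"):
        start_mses = np.array([mse(s) for s in starts])
        best_start_mse = float(np.min(start_mses)) if len(start_mses) else np.inf

        candidates: list[tuple[float, tuple[float, ...]]] = []
        for s in starts:
            try:
                res = _least_squares(
                    residuals,
                    s,
                    bounds=(lo, hi),
                    max_nfev=max_iterations * (n_params + 1),
                    xtol=max(tolerance, 1e-15),
                    ftol=max(tolerance, 1e-15),
                    gtol=max(tolerance, 1e-15),
                )
            except (ValueError, FloatingPointError):
                continue
            val = mse(res.x)
            if np.isfinite(val):
                candidates.append((val, tuple(float(v) for v in res.x)))

    if not candidates:
        raise EstimationError(
            f"all {len(starts)} starts failed (best start MSE {best_start_mse:g})"
        )

    # stable tie-break: lowest MSE, then lexicographically smallest params
    best_mse, best_params = min(candidates, key=lambda c: (c[0], c[1]))
    converged = best_mse <= best_start_mse * (1.0 + 1e-12) + 1e-300
    return ParamEstimate(
        names=tuple(names) if names else tuple(f"p{i}" for i in range(n_params)),
        values=np.array(best_params),
        rmsd=float(np.sqrt(best_mse)),
        converged=bool(converged),
        n_points=int(y.size),
    )


def _summaries(samples: np.ndarray, ci_level: float):
    alpha = (1.0 - ci_level) / 2.0
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1) if samples.shape[0] > 1 else np.zeros(
        samples.shape[1]
    )
    ci_low = np.quantile(samples, alpha, axis=0)
    ci_high = np.quantile(samples, 1.0 - alpha, axis=0)
    return mean, sd, ci_low, ci_high


def bootstrap_parameters(
    model: ModelFn,
    x: Sequence[float],
    y: Sequence[float],
    fit: ParamEstimate,
    bounds: Sequence[tuple[float, float]],
    n_boot: int,
    seed: int,
    scheme: Literal["residual", "case"] = "residual",
    ci_level: float = 0.95,
    max_iterations: int = 1000,
    tolerance: float = 1e-14,
) -> ParamDistribution:
    """Bootstrap the parameters of a converged fit.

    ``scheme="residual"`` resamples residuals around the fitted curve and
    refits (appropriate for a single time series); ``scheme="case"``
    resamples data points with replacement within each distinct x level
    (appropriate for replicated rate tables).  Each refit starts from the
    point estimate.  Refits that fail are dropped and counted; more than 50%
    failures is an estimation error.
    """
    if not fit.converged:
        raise EstimationError("bootstrap requires a converged base fit")
    if n_boot < 2:
        raise ContractError("n_boot must be >= 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        yhat = model(x, fit.values)
    residuals = y - yhat
    rng = np.random.default_rng(seed)

    if scheme == "case":
        level_idx = [np.flatnonzero(x == lv) for lv in np.unique(x)]

    samples: list[tuple[float, ...]] = []
    n_failed = 0
    for _ in range(n_boot):
        if scheme == "residual":
            y_star = yhat + rng.choice(residuals, size=residuals.size, replace=True)
            x_star = x
        elif scheme == "case":
            pick = np.concatenate(
                [rng.choice(idx, size=idx.size, replace=True) for idx in level_idx]
            )
            x_star, y_star = x[pick], y[pick]
        else:
            raise ValueError(f"unknown bootstrap scheme {scheme!r}")
        try:
            refit = minimize_rmsd(
                model,
                x_star,
                y_star,
                bounds,
                starts=fit.values[None, :],
                names=fit.names,
                max_iterations=max_iterations,
                tolerance=tolerance,
            )
        except EstimationError:
            n_failed += 1
            continue
        samples.append(tuple(refit.values))

    if n_failed > n_boot // 2:
        raise EstimationError(f"{n_failed}/{n_boot} bootstrap refits failed")

    arr = np.array(samples, dtype=float)
    mean, sd, ci_low, ci_high = _summaries(arr, ci_level)
    return ParamDistribution(
        names=fit.names,
        samples=arr,
        mean=mean,
        sd=sd,
        ci_low=ci_low,
        ci_high=ci_high,
        seed=int(seed),
        n_failed=n_failed,
    )


def propagate_uncertainty(
    dist: ParamDistribution,
    derived: Callable[[np.ndarray], float],
    n_mc: int,
    seed: int,
    ci_level: float = 0.95,
) -> DerivedSummary:
    """Monte-Carlo propagation of a derived quantity through the bootstrap cloud.

    Draws parameter vectors by resampling rows of the bootstrap matrix,
    evaluates ``derived`` on each, drops (and counts) non-finite values and
    summarizes the rest with mean, sd and a percentile interval.
    """
    if n_mc < 1:
        raise ContractError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, dist.samples.shape[0], size=n_mc)
    values = np.array(
        [derived(dist.samples[r]) for r in rows], dtype=float
    )
    finite = np.isfinite(values)
    n_dropped = int(n_mc - finite.sum())
    if n_dropped == n_mc:
        raise PropagationError("derived quantity non-finite on every draw")
    values = values[finite]
    alpha = (1.0 - ci_level) / 2.0
    return DerivedSummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        ci_low=float(np.quantile(values, alpha)),
        ci_high=float(np.quantile(values, 1.0 - alpha)),
        n_mc=int(n_mc),
        n_dropped=n_dropped,
    )
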