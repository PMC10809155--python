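"""Secondary models over condition-level growth rates.

Two secondary models are fitted to the (concentration, mu) pairs produced by
the primary Gompertz stage:

* Monod substrate affinity, ``mu = mu_max * S / (K_S + S)``, yielding the
  half-saturation constant K_S of the growth substrate; and
* linear product inhibition, ``mu = mu_max * (1 - K * P)``, whose extrapolated
  zero-growth concentration ``P_inhib = 1/K`` is the predicted inhibitory
  concentration of the product (here caproic acid).

Rates for the inhibition fit are conventionally normalized to the mean rate
of the replicates at 0 g/L of inhibitor, so mu_max is dimensionless and close
to 1.  A Welch unequal-variances t-test screens each concentration against
the baseline for a significant rate decrease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, EstimationError
from .estimation import (
    DerivedSummary,
    FitConfig,
    ParamDistribution,
    bootstrap_parameters,
    minimize_rmsd,
    propagate_uncertainty,
)
from .speciation import CompoundRegistry, gl_to_mM

#: K_S estimates at or below this bound (g/L) are flagged as collapsed.
KS_LOWER_BOUND = 1e-6

#: Inhibition slopes at or below this value (L/g) are numerically zero:
#: the zero-growth threshold is never reached within the model.
K_SLOPE_EPS = 1e-8


@dataclass(frozen=True)
class RatePoint:
    """One replicate growth rate at one concentration level."""

    x: float  # substrate or inhibitor concentration, g/L
    mu: float  # growth rate, h^-1 (or dimensionless when normalized)
    replicate_id: str = ""
    normalized: bool = False
    no_growth: bool = False

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ContractError("concentration must be >= 0")
        if self.mu < 0:
            raise ContractError("growth rate must be >= 0")


def points_from_frame(df: pd.DataFrame) -> list[RatePoint]:
    """Build RatePoints from a rate-table frame (x_g_l, mu_h, replicate...)."""
    ng = df["no_growth"] if "no_growth" in df.columns else [False] * len(df)
    return [
        RatePoint(
            x=float(r.x_g_l),
            mu=float(r.mu_h),
            replicate_id=str(r.replicate),
            no_growth=bool(n),
        )
        for r, n in zip(df.itertuples(), ng)
    ]


def points_to_frame(points: Iterable[RatePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_g_l": [p.x for p in points],
            "mu_h": [p.mu for p in points],
            "replicate": [p.replicate_id for p in points],
            "normalized": [p.normalized for p in points],
            "no_growth": [p.no_growth for p in points],
        }
    )


# ---------------------------------------------------------------------------
# Monod substrate affinity
# ---------------------------------------------------------------------------

def monod_mu(S, mu_max: float, K_S: float):
    """Monod growth rate: mu = mu_max * S / (K_S + S)."""
    if K_S <= 0:
        raise ContractError("K_S must be > 0")
    S = np.asarray(S, dtype=float)
    out = mu_max * S / (K_S + S)
    return float(out) if out.ndim == 0 else out


def _monod_model(S: np.ndarray, params: np.ndarray) -> np.ndarray:
    mu_max, K_S = params
    return mu_max * S / (np.maximum(K_S, 1e-300) + S)


@dataclass
class MonodFit:
    """Fitted Monod parameters with bootstrap uncertainty."""

    mu_max: float
    K_S: float
    rmsd: float
    uncertainty: ParamDistribution | None = None
    ks_at_bound: bool = False
    n_points: int = 0


def fit_monod(
    points: Sequence[RatePoint],
    config: FitConfig | None = None,
    n_boot: int | None = None,
) -> MonodFit:
    """Fit the Monod model to (S, mu) pairs by RMSD minimization.

    Requires >= 3 distinct concentrations.  Bootstrap uncertainty by case
    resampling stratified by concentration level.  A flat rate profile drives
    K_S to its lower bound, which is flagged rather than treated as an error.
    """
    config = config or FitConfig()
    if n_boot is None:
        n_boot = config.n_boot
    pts = [p for p in points if not p.no_growth]
    S = np.array([p.x for p in pts], dtype=float)
    mu = np.array([p.mu for p in pts], dtype=float)
    if np.unique(S).size < 3:
        raise EstimationError(
            "Monod fit needs rates at >= 3 distinct concentrations"
        )
    mu_max0 = float(np.max(mu))
    if mu_max0 <= 0:
        raise EstimationError("all growth rates are zero")
    # K_S guess: concentration nearest to half-maximal rate
    half_idx = int(np.argmin(np.abs(mu - 0.5 * mu_max0)))
    ks0 = float(max(S[half_idx], 0.01 * np.max(S)))
    bounds = [(1e-8, 2.0 * mu_max0), (KS_LOWER_BOUND, 10.0 * float(np.max(S)))]
    factors = (0.5, 1.0, 1.5)
    starts = np.array(
        [(mu_max0 * f1, ks0 * f2) for f1 in factors for f2 in factors]
    )
    est = minimize_rmsd(
        _monod_model, S, mu, bounds, starts=starts, names=("mu_max", "K_S"),
        max_iterations=config.max_iterations, tolerance=config.tolerance,
    )
    uncertainty = None
    if n_boot and n_boot >= 2:
        uncertainty = bootstrap_parameters(
            _monod_model, S, mu, est, bounds,
            n_boot=n_boot, seed=config.seed, scheme="case",
            ci_level=config.ci_level,
            max_iterations=config.max_iterations, tolerance=config.tolerance,
        )
    mu_max, K_S = est.values
    return MonodFit(
        mu_max=float(mu_max),
        K_S=float(K_S),
        rmsd=est.rmsd,
        uncertainty=uncertainty,
        ks_at_bound=bool(K_S <= 2.0 * KS_LOWER_BOUND),
        n_points=est.n_points,
    )


# ---------------------------------------------------------------------------
# Linear product inhibition
# ---------------------------------------------------------------------------

def linear_inhibition_mu(P, mu_max: float, K: float):
    """Linear inhibition prediction: mu = mu_max * max(0, 1 - K*P)."""
    if K < 0:
        raise ContractError("inhibition slope K must be >= 0")
    P = np.asarray(P, dtype=float)
    out = mu_max * np.maximum(0.0, 1.0 - K * P)
    return float(out) if out.ndim == 0 else out


def _inhibition_model(P: np.ndarray, params: np.ndarray) -> np.ndarray:
    # unclamped line: the fit uses only concentrations where growth occurred
    mu_max, K = params
    return mu_max * (1.0 - K * P)


@dataclass
class NormalizedRates:
    """Rates divided by the mean baseline rate, with the baseline recorded."""

    points: list[RatePoint]
    baseline_x: float
    baseline_mean: float


def normalize_rates(
    points: Sequence[RatePoint], baseline_x: float = 0.0
) -> NormalizedRates:
    """Divide every rate by the mean rate of the replicates at ``baseline_x``."""
    base = [p.mu for p in points if p.x == baseline_x and not p.no_growth]
    if not base:
        raise ContractError(
            f"no growing replicate at baseline concentration {baseline_x}"
        )
    mean = float(np.mean(base))
    if mean == 0:
        raise ZeroDivisionError("baseline mean growth rate is zero")
    normed = [
        replace(p, mu=p.mu / mean, normalized=True) for p in points
    ]
    return NormalizedRates(points=normed, baseline_x=baseline_x, baseline_mean=mean)


@dataclass
class InhibitionFit:
    """Linear inhibition fit with the extrapolated inhibitory concentration.

    ``P_inhib`` is 1/K at the point estimate (the concentration where the
    fitted line crosses zero growth); its mean/sd come from Monte-Carlo
    propagation over the bootstrap K distribution.  ``P_inhib_mM`` converts
    via the compound registry.  When the fitted slope is ~0 the threshold is
    never reached within the model and ``reached`` is False.
    """

    mu_max: float
    K: float
    rmsd: float
    P_inhib: float | None = None
    P_inhib_summary: DerivedSummary | None = None
    P_inhib_mM: float | None = None
    P_inhib_mM_sd: float | None = None
    reached: bool = True
    uncertainty: ParamDistribution | None = None
    n_points: int = 0
    compound: str = "caproate"


def fit_inhibition(
    points: Sequence[RatePoint],
    config: FitConfig | None = None,
    n_boot: int | None = None,
    include_zero_rates: bool = False,
    compound: str = "caproate",
    registry: CompoundRegistry | None = None,
) -> InhibitionFit:
    """Fit the linear inhibition model and extrapolate the inhibitory level.

    No-growth conditions are excluded by default: the model is a linear trend
    fitted on measured rates and extrapolated to zero growth; hard zeros from
    below-threshold wells would bias the slope.  Set ``include_zero_rates``
    to force them in as mu = 0.
    """
    config = config or FitConfig()
    if n_boot is None:
        n_boot = config.n_boot
    if include_zero_rates:
        pts = [replace(p, mu=0.0) if p.no_growth else p for p in points]
    else:
        pts = [p for p in points if not p.no_growth]
    P = np.array([p.x for p in pts], dtype=float)
    mu = np.array([p.mu for p in pts], dtype=float)
    if np.unique(P).size < 3:
        raise EstimationError(
            "inhibition fit needs rates at >= 3 distinct concentrations"
        )
    mu_max0 = float(np.max(mu))
    # slope guess from the line through (0, mu_max0) and the highest level
    p_hi = float(np.max(P))
    mu_hi = float(np.mean(mu[P == p_hi]))
    k0 = max((1.0 - mu_hi / mu_max0) / p_hi if p_hi > 0 else 0.01, 1e-4)
    bounds = [(1e-8, 2.0 * mu_max0), (0.0, 10.0 * k0)]
    factors = (0.5, 1.0, 1.5)
    starts = np.array(
        [(mu_max0 * f1, k0 * f2) for f1 in factors for f2 in factors]
    )
    est = minimize_rmsd(
        _inhibition_model, P, mu, bounds, starts=starts,
        names=("mu_max", "K"),
        max_iterations=config.max_iterations, tolerance=config.tolerance,
    )
    mu_max, K = (float(v) for v in est.values)

    uncertainty = None
    if n_boot and n_boot >= 2:
        uncertainty = bootstrap_parameters(
            _inhibition_model, P, mu, est, bounds,
            n_boot=n_boot, seed=config.seed, scheme="case",
            ci_level=config.ci_level,
            max_iterations=config.max_iterations, tolerance=config.tolerance,
        )

    fit = InhibitionFit(
        mu_max=mu_max, K=K, rmsd=est.rmsd,
        uncertainty=uncertainty, n_points=est.n_points, compound=compound,
    )
    if K <= K_SLOPE_EPS:
        fit.reached = False
        return fit
    fit.P_inhib = 1.0 / K
    if uncertainty is not None:
        k_idx = est.names.index("K")
        summary = propagate_uncertainty(
            uncertainty,
            lambda params: 1.0 / params[k_idx] if params[k_idx] > 0 else np.nan,
            n_mc=config.n_mc,
            seed=config.seed + 1,
            ci_level=config.ci_level,
        )
        fit.P_inhib_summary = summary
        fit.P_inhib_mM_sd = gl_to_mM(summary.sd, compound, registry)
    fit.P_inhib_mM = gl_to_mM(fit.P_inhib, compound, registry)
    return fit


# ---------------------------------------------------------------------------
# Welch significance screening
# ---------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    significant: bool
    degenerate: bool = False


def welch_test(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05
) -> WelchResult:
    """Welch's unequal-variances t-test (two-sided).

    Degenerate inputs (both variances zero) are resolved by the limit of the
    statistic: equal means give t = 0, p = 1; unequal means give p = 0 with
    the degenerate flag set.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0,
                               significant=False)
        return WelchResult(t=math.inf, df=float(a.size + b.size - 2), p=0.0,
                           significant=True, degenerate=True)
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p),
                       significant=bool(p < alpha))


def screen_inhibition_significance(
    points: Sequence[RatePoint],
    baseline_x: float = 0.0,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Welch-test each concentration's rates against the baseline rates.

    Returns one row per non-baseline concentration: (x, mean mu, t, df, p,
    significant).  ``holm`` applies a Holm step-down correction across the
    screen (off by default: the screen mirrors uncorrected pairwise testing).
    """
    base = [p.mu for p in points if p.x == baseline_x]
    if len(base) < 2:
        raise ContractError(
            f"baseline group at {baseline_x} needs n >= 2, got {len(base)}"
        )
    levels = sorted({p.x for p in points} - {baseline_x})
    rows = []
    for lv in levels:
        grp = [p.mu for p in points if p.x == lv]
        res = welch_test(grp, base, alpha=alpha)
        rows.append(
            {
                "x_g_l": lv,
                "mean_mu": float(np.mean(grp)),
                "n": len(grp),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "significant": res.significant,
            }
        )
    table = pd.DataFrame(rows)
    if holm and len(table):
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        table["p_holm"] = adj
        table["significant"] = table["p_holm"] < alpha
    return table
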