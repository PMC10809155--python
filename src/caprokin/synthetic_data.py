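"""Synthetic datasets with the statistical structure the analysis assumes.

No raw growth curves are published for the experiments this package models,
so every pipeline stage is exercised on simulated data instead:

* Gompertz-shaped growth curves with multiplicative instrument noise
  (additive Gaussian noise on the log-normalized signal), in replicate;
* a substrate-affinity (K_S) design: glucose levels spanning 0-6 g/L in
  quadruplicate, with Monod-truth growth rates;
* product-inhibition designs: caproate levels 0-12 g/L in quadruplicate,
  with linear-inhibition-truth rates and no-growth wells above the
  threshold;
* balanced-stoichiometry fermentation tables for the electron balance.

Every generator is a pure function of (design, seed): a master seed spawns
one independent substream per replicate via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .balances import BalanceEntry, electrons_per_mol
from .errors import ValidationError
from .gompertz import gompertz_curve
from .growth_io import GrowthCurve
from .secondary_models import RatePoint, linear_inhibition_mu, monod_mu
from .speciation import CompoundRegistry, default_registry

#: Default additive noise on the log-normalized signal (instrument noise is
#: roughly multiplicative on the raw signal).
DEFAULT_CURVE_NOISE = 0.02

#: Default relative noise on simulated replicate growth rates.
DEFAULT_RATE_NOISE = 0.05


@dataclass(frozen=True)
class GrowthDesign:
    """Design for replicate Gompertz curves from one truth."""

    A: float = 1.5
    mu_m: float = 0.05  # h^-1
    lam: float = 8.0  # h
    n_replicates: int = 4
    sampling_times: tuple[float, ...] = tuple(np.linspace(0.0, 120.0, 60))
    noise_sd: float = DEFAULT_CURVE_NOISE  # log-units, additive on y
    signal0: float = 100.0
    condition_id: str = "sim"
    seed: int = 1291007


@dataclass(frozen=True)
class RateDesign:
    """Design for a secondary-model rate table.

    ``truth`` is (mu_max, K_S) for kind="ks" or (mu_max, K) for
    kind="inhibition"; ``noise_sd`` is relative Gaussian noise on mu.
    """

    kind: str  # "ks" | "inhibition"
    truth: tuple[float, float]
    grid: tuple[float, ...]
    n_replicates: int = 4
    noise_sd: float = DEFAULT_RATE_NOISE
    lag_inflation: float = 0.0  # lam(P) = lam0 * (1 + c*P) for curve output
    seed: int = 1291007


#: Glucose levels of the 96-well substrate-affinity experiment (g/L),
#: quadruplicate, spanning well below and above K_S ~ 0.35 g/L.
KS_HIGH_TRYPTONE = RateDesign(
    kind="ks",
    truth=(0.06, 0.35),
    grid=(0.0, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0),
)

#: Caproate levels tested for L. mucosae (LM), g/L, quadruplicate.
INHIBITION_LM = RateDesign(
    kind="inhibition",
    truth=(1.0, 1.0 / 13.6),
    grid=(0.0, 2.0, 4.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0),
)

#: Caproate levels tested for L. rhamnosus (LR), g/L, quadruplicate.
INHIBITION_LR = RateDesign(
    kind="inhibition",
    truth=(1.0, 1.0 / 8.9),
    grid=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0),
)

NAMED_DESIGNS: dict[str, RateDesign] = {
    "ks_high_tryptone": KS_HIGH_TRYPTONE,
    "inhibition_lm": INHIBITION_LM,
    "inhibition_lr": INHIBITION_LR,
}


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_growth_curve(design: GrowthDesign) -> list[GrowthCurve]:
    """Simulate replicate growth curves on one Gompertz truth.

    y(t) = Gompertz(t) + N(0, noise_sd) on the log-normalized scale; the raw
    signal is signal0 * exp(y), i.e. noise is multiplicative on the signal.
    """
    t = np.asarray(design.sampling_times, dtype=float)
    y_true = gompertz_curve(t, design.A, design.mu_m, design.lam)
    curves = []
    for rep, rng in enumerate(_substreams(design.seed, design.n_replicates)):
        y = y_true + rng.normal(0.0, design.noise_sd, size=t.size)
        curves.append(
            GrowthCurve(
                replicate_id=f"r{rep + 1}",
                condition_id=design.condition_id,
                times=t,
                signals=design.signal0 * np.exp(y),
                meta={"A": design.A, "mu_m": design.mu_m, "lam": design.lam},
            )
        )
    return curves


def _rate_table(design: RateDesign, mu_of_x, no_growth_of_x) -> pd.DataFrame:
    streams = _substreams(design.seed, design.n_replicates)
    rows = []
    for rep, rng in enumerate(streams):
        for x in design.grid:
            mu_true = mu_of_x(x)
            if no_growth_of_x(x):
                rows.append(
                    {"x_g_l": x, "mu_h": 0.0, "replicate": f"r{rep + 1}",
                     "no_growth": True}
                )
                continue
            mu = mu_true * (1.0 + rng.normal(0.0, design.noise_sd))
            rows.append(
                {"x_g_l": x, "mu_h": max(mu, 0.0), "replicate": f"r{rep + 1}",
                 "no_growth": False}
            )
    return pd.DataFrame(rows).sort_values(["x_g_l", "replicate"], ignore_index=True)


def simulate_ks_experiment(design: RateDesign = KS_HIGH_TRYPTONE) -> pd.DataFrame:
    """Rate table for the substrate-affinity design.

    mu at each glucose level follows the Monod truth with relative Gaussian
    noise per replicate; S = 0 wells are no-growth.
    """
    if design.kind != "ks":
        raise ValueError("design.kind must be 'ks'")
    mu_max, K_S = design.truth
    return _rate_table(
        design,
        mu_of_x=lambda s: monod_mu(s, mu_max, K_S),
        no_growth_of_x=lambda s: s == 0.0,
    )


def simulate_inhibition_experiment(design: RateDesign = INHIBITION_LM) -> pd.DataFrame:
    """Rate table for the product-inhibition design.

    mu at each caproate level follows the linear-inhibition truth; levels at
    or beyond the threshold 1/K are no-growth wells.
    """
    if design.kind != "inhibition":
        raise ValueError("design.kind must be 'inhibition'")
    if 0.0 not in design.grid:
        raise ValidationError("inhibition design must include the 0 baseline")
    mu_max, K = design.truth
    return _rate_table(
        design,
        mu_of_x=lambda p: linear_inhibition_mu(p, mu_max, K),
        no_growth_of_x=lambda p: 1.0 - K * p <= 0.0,
    )


def simulate_inhibition_curves(
    design: RateDesign,
    growth: GrowthDesign = GrowthDesign(),
) -> list[GrowthCurve]:
    """Full growth curves for an inhibition design.

    Each concentration level reuses the growth design but scales mu_m by the
    inhibition truth and, when ``design.lag_inflation`` > 0, inflates the lag
    as lam(P) = lam0 * (1 + c*P) -- emulating the longer lag phases observed
    at higher caproate levels.  No-growth levels produce flat (noise-only)
    curves.
    """
    mu_max_rel, K = design.truth
    curves: list[GrowthCurve] = []
    for i, p in enumerate(design.grid):
        factor = 1.0 - K * p
        cond = f"P{p:g}"
        sub = replace(
            growth,
            condition_id=cond,
            seed=growth.seed + 7919 * i,
            mu_m=growth.mu_m * mu_max_rel * max(factor, 0.0),
            lam=growth.lam * (1.0 + design.lag_inflation * p),
        )
        if factor <= 0.0:
            flat = replace(sub, A=1e-9, mu_m=0.0)
            level_curves = simulate_growth_curve(flat)
        else:
            level_curves = simulate_growth_curve(sub)
        for c in level_curves:
            c.meta["caproate_g_l"] = p
        curves.extend(level_curves)
    return curves


def simulate_balance_dataset(
    stoichiometry: Mapping[str, float],
    extent: float,
    noise_sd: float = 0.0,
    seed: int = 1291007,
    registry: CompoundRegistry | None = None,
) -> list[BalanceEntry]:
    """Balance entries from a balanced reaction run to a given extent (mol/L).

    ``stoichiometry`` maps compound names to signed molar coefficients
    (substrates negative).  The reaction must be electron-balanced under the
    degree-of-reduction convention; relative Gaussian noise can be added to
    each concentration change.
    """
    registry = registry or default_registry()
    if extent <= 0:
        raise ValidationError("reaction extent must be > 0")
    e_net = sum(
        coef * electrons_per_mol(registry[name].formula)
        for name, coef in stoichiometry.items()
    )
    e_in = sum(
        -coef * electrons_per_mol(registry[name].formula)
        for name, coef in stoichiometry.items()
        if coef < 0
    )
    if abs(e_net) > 1e-9 * max(e_in, 1.0):
        raise ValidationError(
            f"reaction is not electron-balanced (net {e_net:g} e-/extent)"
        )
    rng = np.random.default_rng(seed)
    entries = []
    for name, coef in stoichiometry.items():
        spec = registry[name]
        delta = coef * extent * spec.molar_mass
        if noise_sd > 0:
            delta *= 1.0 + rng.normal(0.0, noise_sd)
        if coef < 0:
            role = "substrate"
        elif name in ("hydrogen", "carbon_dioxide", "H2", "CO2"):
            role = "gas"
        elif name == "biomass":
            role = "biomass"
        else:
            role = "product"
        entries.append(BalanceEntry(compound=spec, delta_conc=delta, role=role))
    return entries


#: The chain-elongation stoichiometry (reverse beta-oxidation):
#: 1.5 glucose -> 1 caproate + 3 CO2 + 2 H2 + 1 H2O.
CHAIN_ELONGATION = {
    "glucose": -1.5, "caproate": 1.0, "carbon_dioxide": 3.0,
    "hydrogen": 2.0, "water": 1.0,
}

#: Homofermentative glycolysis: 1 glucose -> 2 lactate.
HOMOLACTIC = {"glucose": -1.0, "lactate": 2.0}

#: Heterofermentative phosphoketolase pathway:
#: 1 glucose -> 1 lactate + 1 ethanol + 1 CO2.
HETEROLACTIC = {
    "glucose": -1.0, "lactate": 1.0, "ethanol": 1.0, "carbon_dioxide": 1.0,
}
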