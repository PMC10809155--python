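"""Biomass bookkeeping: VSS, biomass yield and electron balances.

VSS (volatile suspended solids) is the biomass proxy: the mass lost between
drying at 105 C (m1) and ignition at 550 C (m2), per litre filtered.  The
biomass yield on glucose is the ratio of biomass formed (VSS corrected for
the inoculum contribution) to glucose consumed.

The electron balance uses the degree-of-reduction convention: each compound
carries 4C + H - 2O - 3N electron equivalents per mole (relative to CO2,
H2O and NH3, so CO2 and H2O carry none).  A recovery fraction near 1 means
every fermentation product was measured; an open balance points to missed
products (e.g. ethanol escaping the organic-acid analytics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .errors import ContractError, ValidationError
from .speciation import (
    ELECTRONS_PER_ATOM,
    CompoundRegistry,
    CompoundSpec,
    default_registry,
)

#: Grams of chemical oxygen demand per mole of electrons (O2/4 = 8 g/e-mol).
G_COD_PER_E_MOL = 8.0

Role = Literal["substrate", "product", "biomass", "gas"]


@dataclass(frozen=True)
class VSSMeasurement:
    """One filter's masses: dried (m1, 105 C) and ashed (m2, 550 C)."""

    volume_filtered: float  # L
    mass_dried: float  # g
    mass_ashed: float  # g
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.volume_filtered <= 0:
            raise ValidationError("filtered volume must be > 0")
        if self.mass_ashed < 0 or self.mass_dried < self.mass_ashed:
            raise ValidationError(
                "dried mass must be >= ashed mass >= 0 "
                "(VSS is the mass lost on ignition)"
            )


def vss_concentration(m: VSSMeasurement) -> float:
    """VSS in g/L: (m1 - m2) / V, the ignition loss per filtered volume."""
    return (m.mass_dried - m.mass_ashed) / m.volume_filtered


def mean_vss(measurements: Sequence[VSSMeasurement]) -> float:
    """Average VSS over replicate filters (samples are run in duplicate)."""
    if not measurements:
        raise ContractError("need at least one VSS measurement")
    return float(np.mean([vss_concentration(m) for m in measurements]))


@dataclass(frozen=True)
class YieldInput:
    glucose_initial: float  # g/L
    glucose_final: float  # g/L
    vss_final: float  # g/L
    vss_inoculum_contribution: float = 0.0  # g/L

    def __post_init__(self) -> None:
        if not self.glucose_initial >= self.glucose_final >= 0:
            raise ValidationError(
                "need glucose_initial >= glucose_final >= 0"
            )


def biomass_yield(inp: YieldInput) -> float:
    """Biomass yield Y_X/S in g biomass per g glucose consumed."""
    delta_s = inp.glucose_initial - inp.glucose_final
    if delta_s <= 0:
        raise ZeroDivisionError("no glucose was consumed")
    delta_x = inp.vss_final - inp.vss_inoculum_contribution
    if delta_x < 0:
        warnings.warn(
            "final VSS below the inoculum contribution; yield is negative",
            stacklevel=2,
        )
    return delta_x / delta_s


def electrons_per_mol(formula: Mapping[str, float]) -> float:
    """Degree-of-reduction electrons per mole: 4C + H - 2O - 3N."""
    if not formula or all(n == 0 for n in formula.values()):
        raise ContractError("formula must contain at least one atom")
    if any(n < 0 for n in formula.values()):
        raise ContractError("atom counts must be non-negative")
    return sum(ELECTRONS_PER_ATOM[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class BalanceEntry:
    """One row of a balance table: a compound and its concentration change."""

    compound: str | CompoundSpec
    delta_conc: float  # g/L; consumed negative, produced positive
    role: Role


@dataclass
class ElectronBalance:
    """Electron ledger in milliequivalents (mmol e-/L) per entry."""

    entries: list[dict]
    consumed_meq: float
    recovered_meq: float
    recovery_fraction: float

    def warning(self) -> str | None:
        if self.recovery_fraction < 0.9:
            return (
                f"open electron balance: recovery "
                f"{self.recovery_fraction:.3f} < 0.9 - products likely missed"
            )
        if self.recovery_fraction > 1.1:
            return (
                f"electron balance over-closed: recovery "
                f"{self.recovery_fraction:.3f} > 1.1 - check the substrates"
            )
        return None


def electron_balance(
    entries: Sequence[BalanceEntry],
    registry: CompoundRegistry | None = None,
) -> ElectronBalance:
    """Compute the degree-of-reduction electron balance over a fermentation.

    Each entry's |delta_conc| is converted to mmol/L and multiplied by the
    compound's electrons per mole.  Recovery is the electron sum over
    products, biomass and gases divided by the sum over substrates.
    """
    registry = registry or default_registry()
    if not any(e.role == "substrate" for e in entries):
        raise ContractError("balance needs at least one substrate entry")
    rows = []
    consumed = 0.0
    recovered = 0.0
    for e in entries:
        spec = e.compound if isinstance(e.compound, CompoundSpec) else registry[e.compound]
        mmol_l = abs(e.delta_conc) / spec.molar_mass * 1000.0
        meq = mmol_l * spec.electrons_per_mol
        rows.append(
            {
                "compound": spec.name,
                "role": e.role,
                "delta_g_l": e.delta_conc,
                "mmol_l": mmol_l,
                "e_meq_l": meq,
                "g_cod_l": meq * G_COD_PER_E_MOL / 1000.0,
            }
        )
        if e.role == "substrate":
            consumed += meq
        else:
            recovered += meq
    if consumed == 0:
        raise ContractError("substrate entries carry zero electrons")
    return ElectronBalance(
        entries=rows,
        consumed_meq=consumed,
        recovered_meq=recovered,
        recovery_fraction=recovered / consumed,
    )
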