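"""Weak-acid speciation and unit conversions.

Caproic acid (pKa 4.88) is toxic mainly in its undissociated (protonated),
membrane-permeant form.  At a given pH the undissociated fraction of a
monoprotic weak acid follows Henderson-Hasselbalch:

    fraction = 1 / (1 + 10**(pH - pKa))

This module also houses the compound registry (formula, molar mass, pKa)
used for g/L <-> mM conversions and for the electron balances.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Literal, Mapping

import yaml

from .errors import ContractError, RegistryError

#: Degree-of-reduction electron counts per atom (relative to CO2, H2O, NH3).
ELECTRONS_PER_ATOM = {"C": 4.0, "H": 1.0, "O": -2.0, "N": -3.0}

_ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}


@dataclass(frozen=True)
class CompoundSpec:
    """A registry entry: elemental composition, molar mass and optional pKa."""

    name: str
    formula: Mapping[str, float]
    molar_mass: float
    pKa: float | None = None
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be > 0")
        if self.pKa is not None and not (0 < self.pKa < 14):
            raise ValueError(f"{self.name}: pKa must lie in (0, 14)")
        formula_mass = sum(
            _ATOMIC_WEIGHTS[el] * n for el, n in self.formula.items()
        )
        if abs(formula_mass - self.molar_mass) > 1e-3 * self.molar_mass:
            raise ValueError(
                f"{self.name}: molar mass {self.molar_mass} inconsistent with "
                f"formula mass {formula_mass:.3f}"
            )

    @property
    def electrons_per_mol(self) -> float:
        """Degree-of-reduction electrons per mole (4C + H - 2O - 3N)."""
        return sum(
            ELECTRONS_PER_ATOM[el] * n for el, n in self.formula.items()
        )


class CompoundRegistry:
    """Lookup of compounds by name or alias (case-insensitive)."""

    def __init__(self, compounds: Mapping[str, CompoundSpec]):
        self._by_name: dict[str, CompoundSpec] = {}
        for spec in compounds.values():
            self._by_name[spec.name.lower()] = spec
            for alias in spec.aliases:
                self._by_name[alias.lower()] = spec

    def __getitem__(self, name: str) -> CompoundSpec:
        try:
            return self._by_name[name.lower()]
        except KeyError:
            raise RegistryError(f"unknown compound {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._by_name

    @classmethod
    def from_yaml(cls, path=None) -> "CompoundRegistry":
        """Load a registry; with no path, the packaged default is used."""
        if path is None:
            ref = importlib.resources.files("caprokin.data") / "compounds.yaml"
            raw = yaml.safe_load(ref.read_text())
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        compounds = {}
        for name, entry in raw.items():
            compounds[name] = CompoundSpec(
                name=name,
                formula=dict(entry["formula"]),
                molar_mass=float(entry["molar_mass"]),
                pKa=float(entry["pKa"]) if "pKa" in entry else None,
                aliases=tuple(entry.get("aliases", ())),
            )
        return cls(compounds)


_default_registry: CompoundRegistry | None = None


def default_registry() -> CompoundRegistry:
    """The packaged registry, loaded once per process."""
    global _default_registry
    if _default_registry is None:
        _default_registry = CompoundRegistry.from_yaml()
    return _default_registry


def undissociated_fraction(pH: float, pKa: float) -> float:
    """Henderson-Hasselbalch undissociated (protonated) fraction in (0, 1)."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def _resolve(compound, registry: CompoundRegistry | None) -> CompoundSpec:
    if isinstance(compound, CompoundSpec):
        return compound
    return (registry or default_registry())[str(compound)]


def gl_to_mM(conc_g_l: float, compound, registry=None) -> float:
    """Convert g/L to mM via the compound's molar mass."""
    if conc_g_l < 0:
        raise ContractError("concentration must be >= 0")
    spec = _resolve(compound, registry)
    return conc_g_l * 1000.0 / spec.molar_mass


def mM_to_gl(conc_mM: float, compound, registry=None) -> float:
    """Convert mM to g/L; exact inverse of :func:`gl_to_mM`."""
    if conc_mM < 0:
        raise ContractError("concentration must be >= 0")
    spec = _resolve(compound, registry)
    return conc_mM * spec.molar_mass / 1000.0


@dataclass
class AcidSpeciation:
    """Total vs undissociated concentrations of a weak acid at one pH."""

    compound: str
    pH: float
    total_g_l: float
    total_mM: float
    undissociated_g_l: float
    undissociated_mM: float
    fraction_undissociated: float

    def as_dict(self) -> dict:
        return {
            "compound": self.compound,
            "pH": self.pH,
            "total_g_l": self.total_g_l,
            "total_mM": self.total_mM,
            "undissociated_g_l": self.undissociated_g_l,
            "undissociated_mM": self.undissociated_mM,
            "fraction_undissociated": self.fraction_undissociated,
        }


def speciate(
    total: float,
    pH: float,
    compound,
    unit: Literal["g_l", "mM"] = "g_l",
    registry: CompoundRegistry | None = None,
) -> AcidSpeciation:
    """Speciate a total weak-acid concentration at a given pH.

    ``unit`` declares the unit of ``total``; both unit systems are populated
    in the result.  The compound must have a pKa in the registry.
    """
    if total < 0:
        raise ContractError("total concentration must be >= 0")
    spec = _resolve(compound, registry)
    if spec.pKa is None:
        raise ContractError(f"{spec.name} has no pKa; cannot speciate")
    if unit == "g_l":
        total_g_l = float(total)
        total_mM = gl_to_mM(total_g_l, spec)
    elif unit == "mM":
        total_mM = float(total)
        total_g_l = mM_to_gl(total_mM, spec)
    else:
        raise ValueError(f"unknown unit {unit!r}")
    frac = undissociated_fraction(pH, spec.pKa)
    return AcidSpeciation(
        compound=spec.name,
        pH=float(pH),
        total_g_l=total_g_l,
        total_mM=total_mM,
        undissociated_g_l=total_g_l * frac,
        undissociated_mM=total_mM * frac,
        fraction_undissociated=frac,
    )
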