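"""Read, validate, group and normalize replicated growth-signal time series.

Growth is monitored as an optical-density proxy (laser backscatter in serum
bottles, total-absorption values from live imaging in 96-well plates).  Each
replicate of each condition yields one :class:`GrowthCurve`; fitting operates
on curves normalized to their initial signal (:func:`normalize`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

NormalizationMode = Literal["log", "linear"]

#: Signals smaller than this fraction of the curve maximum are rejected as
#: below the instrument detection floor rather than silently clipped.
DETECTION_FLOOR = 1e-6

CURVE_COLUMNS = ("time_h", "signal", "replicate", "condition_id")
CONDITION_COLUMNS = ("condition_id",)

_TIME_FACTORS = {"s": 1.0 / 3600.0, "min": 1.0 / 60.0, "h": 1.0}


@dataclass
class GrowthCurve:
    """One replicate's raw signal time series with condition metadata.

    Parameters
    ----------
    replicate_id, condition_id : str
        Labels linking the curve to the experimental design.
    times : array-like
        Time points in hours, strictly increasing, first point >= 0.
    signals : array-like
        Raw instrument signal (arbitrary units), all > 0, length >= 5.
    meta : dict
        Condition attributes (e.g. ``glucose_g_l``, ``caproate_g_l``,
        ``organism``) carried through from the condition table.
    """

    replicate_id: str
    condition_id: str
    times: np.ndarray
    signals: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        tag = f"curve ({self.condition_id!r}, {self.replicate_id!r})"
        if self.times.ndim != 1 or self.signals.ndim != 1:
            raise ValidationError(f"{tag}: times and signals must be 1-D")
        if len(self.times) != len(self.signals):
            raise ValidationError(f"{tag}: times and signals differ in length")
        if len(self.times) < 5:
            raise ValidationError(f"{tag}: needs >= 5 points, got {len(self.times)}")
        if self.times[0] < 0:
            raise ValidationError(f"{tag}: first time point is negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{tag}: times are not strictly increasing")
        if np.any(self.signals <= 0):
            raise ValidationError(f"{tag}: signals must be strictly positive")
        floor = DETECTION_FLOOR * float(np.max(self.signals))
        if np.any(self.signals < floor):
            raise ValidationError(
                f"{tag}: signals below the detection floor "
                f"({DETECTION_FLOOR:g} of the curve maximum)"
            )

    @property
    def signal0(self) -> float:
        """Initial signal, the OD0-equivalent used for normalization."""
        return float(self.signals[0])


@dataclass
class NormalizedCurve:
    """Dimensionless growth signal y(t) normalized to the initial value.

    ``mode="log"`` gives y = ln(signal/signal0) (y starts at 0); ``"linear"``
    gives y = signal/signal0 (y starts at 1).
    """

    times: np.ndarray
    y: np.ndarray
    mode: NormalizationMode
    replicate_id: str = ""
    condition_id: str = ""
    meta: dict = field(default_factory=dict)


def normalize(curve: GrowthCurve, mode: NormalizationMode = "log") -> NormalizedCurve:
    """Normalize a growth curve to its initial signal.

    The log mode is the default because a specific growth rate in h^-1
    is the slope of log-transformed biomass; the linear mode (y = OD/OD0)
    is retained as an option.
    """
    if mode not in ("log", "linear"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    s0 = curve.signal0
    if s0 == 0:
        raise ZeroDivisionError("initial signal is zero")
    ratio = curve.signals / s0
    y = np.log(ratio) if mode == "log" else ratio
    return NormalizedCurve(
        times=curve.times.copy(),
        y=y,
        mode=mode,
        replicate_id=curve.replicate_id,
        condition_id=curve.condition_id,
        meta=dict(curve.meta),
    )


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def read_curves(
    path,
    condition_table,
    time_unit: str = "h",
) -> list[GrowthCurve]:
    """Read a curve CSV plus its condition table into GrowthCurve objects.

    The curve file needs columns ``time_h, signal, replicate, condition_id``;
    the condition table needs ``condition_id`` and may carry any further
    columns (``glucose_g_l``, ``caproate_g_l``, ``organism``, ...), which are
    passed through to ``GrowthCurve.meta``.  ``time_unit`` declares the unit
    of the time column; values are converted to hours on load.
    """
    if time_unit not in _TIME_FACTORS:
        raise ValueError(f"time_unit must be one of {sorted(_TIME_FACTORS)}")
    try:
        # round_trip parsing keeps write->read cycles bit-identical
        curves_df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("curve file %s has no content; returning no curves", path)
        return []
    if curves_df.empty:
        logger.warning("curve file %s is empty; returning no curves", path)
        return []
    _require_columns(curves_df, CURVE_COLUMNS, "curve file")

    cond_df = pd.read_csv(condition_table)
    _require_columns(cond_df, CONDITION_COLUMNS, "condition table")
    cond_df = cond_df.set_index(cond_df["condition_id"].astype(str))

    unknown = set(curves_df["condition_id"].astype(str)) - set(cond_df.index)
    if unknown:
        raise ValidationError(
            f"condition id(s) not in condition table: {sorted(unknown)}"
        )

    dup = curves_df.duplicated(subset=["condition_id", "replicate", "time_h"])
    if dup.any():
        row = curves_df[dup].iloc[0]
        raise ValidationError(
            "duplicated (replicate, time) row for replicate "
            f"{row['replicate']!r} at t={row['time_h']}"
        )

    factor = _TIME_FACTORS[time_unit]
    curves: list[GrowthCurve] = []
    for (cond_id, rep), group in curves_df.groupby(
        ["condition_id", "replicate"], sort=True
    ):
        group = group.sort_values("time_h")
        meta = cond_df.loc[str(cond_id)].drop(labels=["condition_id"]).to_dict()
        curves.append(
            GrowthCurve(
                replicate_id=str(rep),
                condition_id=str(cond_id),
                times=group["time_h"].to_numpy(dtype=float) * factor,
                signals=group["signal"].to_numpy(dtype=float),
                meta=meta,
            )
        )
    return curves


def write_curves(curves: Iterable[GrowthCurve], path) -> None:
    """Write curves back to the CSV dialect accepted by :func:`read_curves`."""
    frames = [
        pd.DataFrame(
            {
                "time_h": c.times,
                "signal": c.signals,
                "replicate": c.replicate_id,
                "condition_id": c.condition_id,
            }
        )
        for c in curves
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(CURVE_COLUMNS))
    )
    out.to_csv(path, index=False)


def write_conditions(curves: Iterable[GrowthCurve], path) -> None:
    """Write one condition-table row per distinct condition in *curves*."""
    rows = {}
    for c in curves:
        rows.setdefault(c.condition_id, {"condition_id": c.condition_id, **c.meta})
    pd.DataFrame(list(rows.values())).to_csv(path, index=False)
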