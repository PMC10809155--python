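"""End-to-end orchestration: curves -> Gompertz fits -> secondary model ->
speciation, with machine-readable reports.

The pipeline is configured from a YAML file (see :class:`PipelineConfig`);
every report embeds the fully resolved configuration and the seed, so a
rerun with the same config reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .estimation import FitConfig
from .gompertz import GROWTH_THRESHOLD, fit_gompertz, summarize_condition
from .growth_io import normalize, read_curves
from .secondary_models import (
    RatePoint,
    fit_inhibition,
    fit_monod,
    normalize_rates,
    screen_inhibition_significance,
)
from .speciation import CompoundRegistry, default_registry, speciate

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    ``secondary`` selects the second-stage model: ``"monod"`` regresses
    condition rates on the substrate column, ``"inhibition"`` on the
    inhibitor column, ``"none"`` stops after the Gompertz stage.
    """

    curves: str
    conditions: str
    output_dir: str
    fit: FitConfig = field(default_factory=FitConfig)
    normalization_mode: str = "log"
    time_unit: str = "h"
    secondary: str = "none"  # none | monod | inhibition
    concentration_column: str = "caproate_g_l"
    baseline_x: float = 0.0
    alpha: float = 0.05
    growth_threshold: float = GROWTH_THRESHOLD
    speciation_ph: float = 5.5
    speciation_compound: str = "caproate"
    compound_registry: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fit_block = raw.pop("fit", {})
        if "seed" not in fit_block:
            raise ValidationError("config must set fit.seed explicitly")
        return cls(fit=FitConfig(**fit_block), **raw)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def run_growth_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write CSV/JSON reports.

    Returns the report dict.  Stages: read + validate curves, normalize,
    per-curve Gompertz fits (with bootstrap uncertainty), per-condition rate
    summaries, optional secondary fit with significance screen, and weak-acid
    speciation of the extrapolated inhibitory concentration.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = (
        CompoundRegistry.from_yaml(config.compound_registry)
        if config.compound_registry
        else default_registry()
    )

    logger.info("reading curves from %s (seed %d)", config.curves, config.fit.seed)
    curves = read_curves(config.curves, config.conditions, config.time_unit)
    logger.info("fitting %d curves", len(curves))

    fit_rows = []
    fits_by_condition: dict[str, list] = {}
    meta_by_condition: dict[str, dict] = {}
    for curve in curves:
        norm = normalize(curve, config.normalization_mode)
        fit = fit_gompertz(
            norm, config.fit, growth_threshold=config.growth_threshold
        )
        fits_by_condition.setdefault(curve.condition_id, []).append(fit)
        meta_by_condition[curve.condition_id] = curve.meta
        row = {
            "condition_id": curve.condition_id,
            "replicate": curve.replicate_id,
            "A": fit.A,
            "mu_m_h": fit.mu_m,
            "lam_h": fit.lam,
            "rmsd": fit.rmsd,
            "no_growth": fit.no_growth,
        }
        if fit.uncertainty is not None:
            for name, sd in zip(fit.uncertainty.names, fit.uncertainty.sd):
                row[f"{name}_sd"] = float(sd)
        fit_rows.append(row)
    fits_df = pd.DataFrame(fit_rows)
    fits_df.to_csv(outdir / "gompertz_fits.csv", index=False)

    condition_rows = []
    for cond_id, fits in sorted(fits_by_condition.items()):
        summary = summarize_condition(fits)
        condition_rows.append(
            {
                "condition_id": cond_id,
                "mean_mu_h": summary.mean_mu,
                "sd_mu_h": summary.sd_mu,
                "n": summary.n,
                "n_no_growth": summary.n_no_growth,
                **meta_by_condition[cond_id],
            }
        )
    cond_df = pd.DataFrame(condition_rows)
    cond_df.to_csv(outdir / "condition_rates.csv", index=False)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": config.resolved(),
        "n_curves": len(curves),
        "conditions": condition_rows,
    }

    if config.secondary != "none":
        points = []
        for cond_id, fits in fits_by_condition.items():
            x = float(meta_by_condition[cond_id][config.concentration_column])
            for f in fits:
                points.append(
                    RatePoint(
                        x=x,
                        mu=0.0 if f.no_growth else f.mu_m,
                        replicate_id=f.replicate_id,
                        no_growth=f.no_growth,
                    )
                )
        if config.secondary == "monod":
            mfit = fit_monod(points, config.fit)
            report["monod"] = {
                "mu_max_h": mfit.mu_max,
                "K_S_g_l": mfit.K_S,
                "rmsd": mfit.rmsd,
                "ks_at_bound": mfit.ks_at_bound,
                "K_S_sd": float(mfit.uncertainty.sd[1])
                if mfit.uncertainty is not None
                else None,
                "n_boot": config.fit.n_boot,
                "seed": config.fit.seed,
            }
        elif config.secondary == "inhibition":
            normed = normalize_rates(points, config.baseline_x)
            ifit = fit_inhibition(
                normed.points,
                config.fit,
                compound=config.speciation_compound,
                registry=registry,
            )
            block = {
                "mu_max_normalized": ifit.mu_max,
                "K_l_g": ifit.K,
                "rmsd": ifit.rmsd,
                "baseline_mean_mu_h": normed.baseline_mean,
                "reached": ifit.reached,
                "n_boot": config.fit.n_boot,
                "seed": config.fit.seed,
            }
            if ifit.reached:
                block["P_inhib_g_l"] = ifit.P_inhib
                block["P_inhib_mM"] = ifit.P_inhib_mM
                if ifit.P_inhib_summary is not None:
                    block["P_inhib_g_l_sd"] = ifit.P_inhib_summary.sd
                    block["P_inhib_mM_sd"] = ifit.P_inhib_mM_sd
                    block["P_inhib_ci"] = [
                        ifit.P_inhib_summary.ci_low,
                        ifit.P_inhib_summary.ci_high,
                    ]
                sp = speciate(
                    ifit.P_inhib,
                    config.speciation_ph,
                    config.speciation_compound,
                    unit="g_l",
                    registry=registry,
                )
                block["speciation"] = sp.as_dict()
            report["inhibition"] = block
            screen = screen_inhibition_significance(
                points, config.baseline_x, config.alpha
            )
            screen.to_csv(outdir / "significance.csv", index=False)
            report["significance"] = screen.to_dict(orient="records")
        else:
            raise ValueError(f"unknown secondary model {config.secondary!r}")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    logger.info("report written to %s", outdir / "report.json")
    return report
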