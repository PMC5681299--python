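"""End-to-end orchestration: ingest or simulate, fit, report.

``run_analysis`` assembles a cohort (from file or the synthetic generator),
fits the requested models with and/or without gene-generation interactions,
and emits a descriptive summary, an anticipation-effects table (both models
side by side), a full parameter table, and Kaplan-Meier curves — as in-memory
frames and, when an output directory is given, as delimited text and JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import (
    CarrierRecord,
    ExclusionLog,
    apply_exclusions,
    build_design,
    code_generations,
    read_cohort,
    summarize_cohort,
    write_cohort,
)
from .coxr import CoxrFit, fit_coxr, hazard_ratio
from .km import km_estimate
from .nrem import NremFit, fit_nrem
from .simulate import CohortConfig, generate_cohort, truth_record

logger = logging.getLogger("anticipation")

__all__ = ["RunConfig", "ResultBundle", "run_analysis", "assemble_cohort"]


@dataclass
class RunConfig:
    """One analysis run: exactly one of ``input_path`` / ``cohort_config``."""

    input_path: str | Path | None = None
    cohort_config: CohortConfig | None = None
    models: tuple[str, ...] = ("nrem", "coxr")
    interactions: bool | str = "both"  # False, True or "both"
    out_dir: str | Path | None = None
    seed: int = 0
    verbosity: int = logging.INFO

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.cohort_config is None):
            raise ValueError("set exactly one of input_path / cohort_config")
        bad = set(self.models) - {"nrem", "coxr"}
        if bad:
            raise ValueError(f"unknown model(s): {sorted(bad)}")
        if self.interactions not in (True, False, "both"):
            raise ValueError("interactions must be True, False or 'both'")

    @property
    def interaction_modes(self) -> tuple[bool, ...]:
        if self.interactions == "both":
            return (False, True)
        return (bool(self.interactions),)


@dataclass
class ResultBundle:
    cohort: list[CarrierRecord]
    exclusion_log: ExclusionLog
    summary: pd.DataFrame
    fits: dict[tuple[str, bool], NremFit | CoxrFit]
    anticipation_table: pd.DataFrame
    full_table: pd.DataFrame
    km_curves: dict
    truth: dict | None = None

    @property
    def all_converged(self) -> bool:
        return all(f.converged for f in self.fits.values())


def assemble_cohort(carriers: Sequence[CarrierRecord]):
    """Apply the standard assembly: generation coding then exclusions."""
    coded = code_generations(carriers)
    retained, log = apply_exclusions(coded)
    logger.info(
        "exclusion cascade: intake %d; dual-carrier parents %d; unknown sex %d; "
        "missing age %d; retained %d",
        log.intake,
        log.counts["dual_carrier_parents"],
        log.counts["unknown_sex"],
        log.counts["missing_age"],
        log.retained,
    )
    return retained, log


def _fit_rows(model: str, inter: bool, fit) -> list[dict]:
    rows = []
    for name, est in fit.estimates.items():
        se = fit.se.get(name, math.nan)
        lo, hi = fit.ci95.get(name, (math.nan, math.nan))
        row = {
            "model": model.upper().replace("COXR", "COX-R"),
            "interactions": inter,
            "parameter": name,
            "estimate": est,
            "ci_lower": lo,
            "ci_upper": hi,
            "se": se,
            "wald_p": fit.wald_p.get(name, math.nan),
        }
        if model == "coxr" and not name.startswith("var_"):
            row["hazard_ratio"] = round(hazard_ratio(est), 2)
        rows.append(row)
    return rows


def run_analysis(config: RunConfig) -> ResultBundle:
    """Run the full pipeline described by ``config``."""
    logging.basicConfig(level=config.verbosity)
    truth = None
    if config.cohort_config is not None:
        cc = dataclasses.replace(config.cohort_config, seed=config.seed)
        carriers, _ = generate_cohort(cc)
        truth = truth_record(cc)
        logger.info("simulated cohort: %d carriers", len(carriers))
    else:
        carriers = read_cohort(config.input_path)
        logger.info("read %d carriers from %s", len(carriers), config.input_path)

    retained, excl = assemble_cohort(carriers)
    design = build_design(retained)
    summary = summarize_cohort(retained)

    ages = np.array([r.age for r in retained], dtype=float)
    events = np.array([r.event for r in retained], dtype=bool)
    genes = np.array([r.gene_category for r in retained])
    km_curves = {"all": km_estimate(ages, events, label="all")}
    km_curves.update(km_estimate(ages, events, strata=genes))

    fits: dict[tuple[str, bool], NremFit | CoxrFit] = {}
    for inter in config.interaction_modes:
        if "nrem" in config.models:
            fit = fit_nrem(retained, design, interactions=inter, seed=config.seed)
            fits[("nrem", inter)] = fit
            logger.info(
                "NREM (interactions=%s): loglik %.3f, converged %s%s",
                inter, fit.loglik, fit.converged,
                "; Var(mu) at boundary" if fit.boundary_var_mu else "",
            )
        if "coxr" in config.models:
            fit = fit_coxr(retained, design, interactions=inter)
            fits[("coxr", inter)] = fit
            logger.info(
                "COX-R (interactions=%s): integrated loglik %.3f, converged %s%s",
                inter, fit.integrated_loglik, fit.converged,
                "; collapsed to plain Cox" if fit.collapsed else "",
            )

    rows = []
    for (model, inter), fit in fits.items():
        rows.extend(_fit_rows(model, inter, fit))
    full_table = pd.DataFrame(rows)
    is_anticipation = full_table["parameter"].str.startswith(("gamma",))
    anticipation_table = full_table[is_anticipation].reset_index(drop=True)

    bundle = ResultBundle(
        cohort=retained,
        exclusion_log=excl,
        summary=summary,
        fits=fits,
        anticipation_table=anticipation_table,
        full_table=full_table,
        km_curves=km_curves,
        truth=truth,
    )
    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not serialisable: {type(obj)}")


def _clean(value):
    """Recursively map non-finite floats to None ("not reached") for JSON."""
    if isinstance(value, (tuple, list)):
        return [_clean(v) for v in value]
    if isinstance(value, dict):
        return {k: _clean(v) for k, v in value.items()}
    if isinstance(value, (float, np.floating)) and not math.isfinite(value):
        return None
    return value


def _summary_json(summary: pd.DataFrame) -> dict:
    return {col: _clean(dict(summary[col].items())) for col in summary.columns}


def _write_bundle(bundle: ResultBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_cohort(bundle.cohort, out_dir / "cohort_analyzed.csv")
    bundle.summary.to_csv(out_dir / "summary.csv")
    (out_dir / "summary.json").write_text(
        json.dumps(_summary_json(bundle.summary), indent=2, default=_json_default)
    )
    bundle.anticipation_table.to_csv(out_dir / "anticipation_effects.csv", index=False)
    bundle.full_table.to_csv(out_dir / "all_parameters.csv", index=False)
    for name, curve in bundle.km_curves.items():
        curve.to_frame().to_csv(out_dir / f"km_{name}.csv", index=False)
    excl = {"counts": bundle.exclusion_log.counts, "retained": bundle.exclusion_log.retained}
    (out_dir / "exclusions.json").write_text(json.dumps(excl, indent=2))
    fits_json = {}
    for (model, inter), fit in bundle.fits.items():
        key = f"{model}_{'interactions' if inter else 'no_interactions'}"
        entry = {
            "estimates": fit.estimates,
            "se": fit.se,
            "ci95": fit.ci95,
            "wald_p": fit.wald_p,
            "converged": fit.converged,
        }
        if isinstance(fit, NremFit):
            entry["loglik"] = fit.loglik
            entry["boundary_var_mu"] = fit.boundary_var_mu
        else:
            entry["integrated_loglik"] = fit.integrated_loglik
            entry["hazard_ratios"] = fit.hazard_ratios
            entry["collapsed"] = fit.collapsed
        fits_json[key] = entry
    (out_dir / "fits.json").write_text(
        json.dumps(_clean(fits_json), indent=2, default=_json_default)
    )
    if bundle.truth is not None:
        (out_dir / "truth.json").write_text(
            json.dumps(bundle.truth, indent=2, default=_json_default)
        )
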