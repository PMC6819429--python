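"""Orchestration of a full MR analysis grid and its reportable data products.

An :class:`AnalysisPlan` names instrument sets, estimation methods and
sensitivity exclusions; :func:`run_plan` evaluates every (set × method) cell,
re-runs IVW after each horizontal-pleiotropy exclusion, and annotates each
result against the multiple-testing threshold. The canonical outputs are data
tables: a flat results table, per-SNP forest-plot rows, and scatter-plot points
with the fitted line; rendering is left to the caller's plotting backend.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .errors import ConfigurationError, MrError, ValidationError
from .estimators import (
    BootstrapSpec,
    MrResult,
    egger_estimate,
    ivw_estimate,
    weighted_median_estimate,
    weighted_mode_estimate,
)
from .summary import ExclusionSet, InstrumentSet, apply_exclusion

logger = logging.getLogger(__name__)

KNOWN_METHODS = ("ivw", "egger", "weighted_median", "weighted_mode")


@dataclass(frozen=True)
class AnalysisPlan:
    """A declarative description of the full analysis grid."""

    instrument_sets: Mapping[str, InstrumentSet]
    methods: Sequence[str] = KNOWN_METHODS
    sensitivity_exclusions: Sequence[ExclusionSet] = ()
    bonferroni_alpha: float = 0.01
    output_dir: Optional[Path] = None
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.instrument_sets:
            raise ValidationError("plan needs at least one instrument set")
        if not self.methods:
            raise ValidationError("plan needs at least one method")
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown:
            raise ValidationError(
                f"unknown method(s): {', '.join(unknown)}; choose from {', '.join(KNOWN_METHODS)}"
            )
        if not (0.0 < self.bonferroni_alpha < 1.0):
            raise ValidationError("bonferroni_alpha must lie in (0, 1)")


@dataclass
class PlanResult:
    """Everything :func:`run_plan` computed, keyed by (instrument set label, method)."""

    results: dict[tuple[str, str], MrResult]
    significant: dict[tuple[str, str], bool]
    skipped: dict[tuple[str, str], str]
    instrument_sets: dict[str, InstrumentSet]
    plan: AnalysisPlan
    log: dict

    def table(self) -> pd.DataFrame:
        """Flat results table, one row per (instrument set × method)."""
        rows = []
        for (set_label, method), r in self.results.items():
            intercept = r.egger_intercept
            rows.append(
                {
                    "instrument_set": set_label,
                    "method": method,
                    "n_snps": r.n_snps,
                    "beta_per_unit": r.beta_per_unit,
                    "se_per_unit": r.se_per_unit,
                    "beta_per_sd": r.beta_per_sd,
                    "or_per_sd": r.or_per_sd,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "q_statistic": r.q_statistic,
                    "q_df": r.q_df,
                    "q_p": r.q_p,
                    "egger_intercept": None if intercept is None else intercept.value,
                    "egger_intercept_se": None if intercept is None else intercept.se,
                    "egger_intercept_p": None if intercept is None else intercept.p_value,
                    "significant": self.significant[(set_label, method)],
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "log": self.log,
            "results": [
                {"instrument_set": k[0], "method": k[1],
                 "significant": self.significant[k], **_result_dict(r)}
                for k, r in self.results.items()
            ],
            "skipped": [
                {"instrument_set": k[0], "method": k[1], "reason": reason}
                for k, reason in self.skipped.items()
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _result_dict(result: MrResult) -> dict:
    d = dataclasses.asdict(result)
    d["per_snp"] = [dataclasses.asdict(s) if not isinstance(s, dict) else s for s in result.per_snp]
    return d


def _estimate(method: str, instruments: InstrumentSet, seed: int) -> MrResult:
    boot = BootstrapSpec(seed=seed)
    if method == "ivw":
        return ivw_estimate(instruments)
    if method == "egger":
        return egger_estimate(instruments)
    if method == "weighted_median":
        return weighted_median_estimate(instruments, bootstrap=boot)
    if method == "weighted_mode":
        return weighted_mode_estimate(instruments, bootstrap=boot)
    raise ValidationError(f"unknown method {method!r}")


def run_plan(plan: AnalysisPlan) -> PlanResult:
    """Evaluate the full grid and the IVW sensitivity re-runs.

    Horizontal-pleiotropy exclusion sets are applied to every instrument set
    that contains all their rsids (an exclusion matching no set is a
    configuration error); vertical-class sets are logged as retained. Estimator
    precondition failures are recorded as skipped cells, not raised. Two runs
    with the same plan and seed produce identical tables.
    """
    results: dict[tuple[str, str], MrResult] = {}
    significant: dict[tuple[str, str], bool] = {}
    skipped: dict[tuple[str, str], str] = {}
    sets: dict[str, InstrumentSet] = dict(plan.instrument_sets)
    retained: list[str] = []

    for set_label, instruments in plan.instrument_sets.items():
        for method in plan.methods:
            key = (set_label, method)
            try:
                results[key] = _estimate(method, instruments, plan.seed)
            except MrError as exc:
                skipped[key] = str(exc)
                logger.warning("skipping %s/%s: %s", set_label, method, exc)

    for exclusion in plan.sensitivity_exclusions:
        if exclusion.pleiotropy_class == "vertical":
            retained.append(exclusion.name)
            logger.info("exclusion %s is vertical pleiotropy; SNPs retained", exclusion.name)
            continue
        matched = False
        for set_label, instruments in plan.instrument_sets.items():
            if not set(exclusion.rsids) <= set(instruments.rsids):
                continue
            matched = True
            reduced = apply_exclusion(instruments, exclusion)
            key = (reduced.label, "ivw")
            sets[reduced.label] = reduced
            try:
                results[key] = _estimate("ivw", reduced, plan.seed)
            except MrError as exc:
                skipped[key] = str(exc)
        if not matched:
            raise ConfigurationError(
                f"exclusion {exclusion.name!r} matches no instrument set in the plan"
            )

    for key, result in results.items():
        significant[key] = result.p_value < plan.bonferroni_alpha

    log = {
        "seed": plan.seed,
        "bonferroni_alpha": plan.bonferroni_alpha,
        "methods": list(plan.methods),
        "instrument_sets": {k: list(v.rsids) for k, v in plan.instrument_sets.items()},
        "exclusions_applied": [
            e.name for e in plan.sensitivity_exclusions if e.pleiotropy_class == "horizontal"
        ],
        "exclusions_retained_vertical": retained,
        "versions": {
            "mrkit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    return PlanResult(
        results=results,
        significant=significant,
        skipped=skipped,
        instrument_sets=sets,
        plan=plan,
        log=log,
    )


def forest_data(result: MrResult) -> pd.DataFrame:
    """Forest-plot table: one OR/CI row per SNP plus a terminal ``Overall`` row."""
    if not result.per_snp:
        raise ValidationError("result carries no per-SNP diagnostics")
    rows = [
        {"label": s.rsid, "or_per_sd": s.or_per_sd, "ci_low": s.ci_low,
         "ci_high": s.ci_high, "p_value": s.p_value}
        for s in result.per_snp
    ]
    rows.append(
        {"label": "Overall", "or_per_sd": result.or_per_sd, "ci_low": result.ci_low,
         "ci_high": result.ci_high, "p_value": result.p_value}
    )
    return pd.DataFrame(rows)


def scatter_data(instruments: InstrumentSet, result: MrResult) -> pd.DataFrame:
    """Scatter-plot table: per-SNP effect pairs and the fitted line.

    The fitted value is intercept + slope × beta_exposure; the intercept is zero
    for every method except MR-Egger. The slope and intercept are attached as
    frame attrs.
    """
    if set(instruments.rsids) != {s.rsid for s in result.per_snp}:
        raise ValidationError("result does not correspond to this instrument set")
    slope = result.beta_per_unit
    intercept = 0.0 if result.egger_intercept is None else result.egger_intercept.value
    frame = pd.DataFrame(
        {
            "rsid": instruments.rsids,
            "beta_exposure": instruments.beta_exposure,
            "beta_outcome": instruments.beta_outcome,
            "se_outcome": instruments.se_outcome,
            "fitted": intercept + slope * instruments.beta_exposure,
        }
    )
    frame.attrs["slope"] = slope
    frame.attrs["intercept"] = intercept
    frame.attrs["method"] = result.method
    return frame


def write_outputs(plan_result: PlanResult, output_dir: str | Path) -> list[Path]:
    """Write results.tsv, results.json and per-set forest/scatter TSVs; returns the paths."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    table_path = outdir / "results.tsv"
    plan_result.table().to_csv(table_path, sep="\t", index=False)
    written.append(table_path)

    json_path = outdir / "results.json"
    json_path.write_text(plan_result.to_json())
    written.append(json_path)

    for set_label, instruments in plan_result.instrument_sets.items():
        key = (set_label, "ivw")
        if key not in plan_result.results:
            continue
        result = plan_result.results[key]
        safe = set_label.replace(" ", "_").replace("/", "-")
        forest_path = outdir / f"forest_{safe}.tsv"
        forest_data(result).to_csv(forest_path, sep="\t", index=False)
        written.append(forest_path)
        scatter_path = outdir / f"scatter_{safe}.tsv"
        scatter_data(instruments, result).to_csv(scatter_path, sep="\t", index=False)
        written.append(scatter_path)
    return written
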