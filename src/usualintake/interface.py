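"""Input validation, results output, and run provenance.

Validation never raises: it returns a :class:`ValidationReport` listing
every problem with a corrective hint, and the pipeline refuses to run
when any error-severity entry is present.  Results are written as two
CSVs — a rounded one for reports and a full-precision companion — plus a
JSON run manifest recording seeds and fitted parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import DataError
from .recall_model import RecallDataset

__all__ = ["ValidationIssue", "ValidationReport", "validate_input",
           "write_results", "write_manifest"]

logger = logging.getLogger(__name__)


@dataclass
class ValidationIssue:
    severity: str          # "error" | "warning"
    code: str
    message: str
    rows: list = field(default_factory=list)

    def __str__(self):
        loc = f" (rows {self.rows[:10]})" if self.rows else ""
        return f"[{self.severity}] {self.code}: {self.message}{loc}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def add(self, severity, code, message, rows=None):
        self.issues.append(ValidationIssue(severity, code, message, rows or []))

    def __str__(self):
        if not self.issues:
            return "input validation passed with no findings"
        return "\n".join(str(i) for i in self.issues)

    def raise_if_failed(self):
        if not self.passed:
            raise DataError("input validation failed:\n" + str(self))


def validate_input(dataset: RecallDataset, config: AnalysisConfig | None = None) -> ValidationReport:
    """Check the recall dataset against the pipeline's contracts.

    Covers: positive finite weights; finite non-negative intakes; recall
    index uniqueness within person; the nearly-daily zero-share
    threshold; covariate presence; replicate-weight consistency; and —
    when a reference table is configured — coverage of every person.
    Each failure carries a hint on how to correct it.
    """
    report = ValidationReport()
    recalls, persons = dataset.recalls, dataset.persons

    w = persons["weight"].to_numpy(dtype=float)
    bad_w = np.flatnonzero(~np.isfinite(w) | (w <= 0))
    if bad_w.size:
        report.add("error", "nonpositive_weight",
                   "survey weights must be finite and strictly positive "
                   "(use 1.0 for an unweighted sample)",
                   rows=persons.index[bad_w].tolist())

    intake = recalls["intake"].to_numpy(dtype=float)
    bad_i = np.flatnonzero(~np.isfinite(intake) | (intake < 0))
    if bad_i.size:
        report.add("error", "negative_intake",
                   "intakes must be finite and >= 0; fix or drop these rows",
                   rows=bad_i.tolist())

    dup = recalls.duplicated(subset=["person_id", "recall_index"])
    if dup.any():
        report.add("error", "duplicate_recall",
                   "recall_index must be unique within person; renumber the "
                   "repeated recalls", rows=np.flatnonzero(dup).tolist())

    threshold = config.zero_share_threshold if config else 0.05
    zero_share = float(np.mean(intake == 0)) if intake.size else 0.0
    if zero_share > threshold:
        report.add("error", "nearly_daily_violation",
                   f"{zero_share:.1%} of person-days report zero intake "
                   f"(threshold {threshold:.0%}): this component looks "
                   "episodically consumed, which the amount-only model cannot "
                   "analyze; a two-part model is required")
    elif zero_share > 0:
        report.add("warning", "zero_intakes",
                   f"{zero_share:.1%} zero person-days; a half-minimum offset "
                   "will be applied before the transform")

    repw = dataset.replicate_weight_columns
    if repw:
        mat = persons[repw].to_numpy(dtype=float)
        if np.any(~np.isfinite(mat)) or np.any(mat < 0):
            report.add("error", "bad_replicate_weights",
                       "replicate weights must be finite and >= 0 for every person")

    if config is not None:
        for name in config.covariates:
            if name not in persons.columns and name not in recalls.columns:
                report.add("error", "missing_covariate",
                           f"covariate {name!r} not found; available person "
                           f"columns: {list(persons.columns)}")
        if config.subgroup_by and config.subgroup_by not in persons.columns:
            report.add("error", "missing_subgroup",
                       f"subgroup column {config.subgroup_by!r} not found")
        if config.one_day_ratio is None:
            if int((dataset.recalls_per_person() >= 2).sum()) == 0:
                report.add("error", "no_repeated_recalls",
                           "no person has repeated recalls; supply "
                           "one_day_ratio (an external within:between variance "
                           "ratio) to run in one-day mode, and report "
                           "sensitivity analyses over a range of ratios")
        if config.reference_table is not None:
            try:
                probe = persons.copy()
                probe["weight_share"] = 1.0
                config.reference_table.assign(
                    probe, sex_col=config.sex_col, age_col=config.age_col,
                    status_col=config.status_col)
            except DataError as exc:
                report.add("error", "reference_coverage", str(exc))
    return report


def _round_frame(df: pd.DataFrame, pct_decimals: int = 1) -> pd.DataFrame:
    """Report rounding: 1 decimal for percentages; intakes to 1 decimal
    below 100 units, integers above (magnitude-dependent, like printed
    survey tables)."""
    out = df.copy()
    for col in out.columns:
        if not pd.api.types.is_float_dtype(out[col]):
            continue
        if "pct" in col:
            out[col] = out[col].round(pct_decimals)
        else:
            vals = out[col].to_numpy(dtype=float)
            scale = np.nanmax(np.abs(vals)) if np.isfinite(vals).any() else 0.0
            out[col] = out[col].round(0 if scale >= 100 else 1)
    return out


def write_results(results: pd.DataFrame, path, pct_decimals: int = 1) -> Path:
    """Write the rounded results CSV plus a ``*_raw.csv`` full-precision copy.

    SE columns stay empty (not zero) when replication did not run.  The
    raw companion re-reads losslessly at stored precision.
    """
    if results.empty:
        raise DataError("refusing to write an empty results table")
    path = Path(path)
    results.to_csv(path.with_name(path.stem + "_raw" + path.suffix), float_format="%.10g")
    _round_frame(results, pct_decimals=pct_decimals).to_csv(path)
    return path


def write_manifest(path, *, seed: int, config: AnalysisConfig,
                   model=None, extra: dict | None = None) -> Path:
    """Machine-readable provenance for a run (seed, transform, variances,
    simulation sizes, scenario list)."""
    payload = {
        "seed": seed,
        "m": config.m,
        "n_nodes": config.n_nodes,
        "covariates": list(config.covariates),
        "subgroup_by": config.subgroup_by,
        "scenarios": [s.name for s in config.scenarios],
        "one_day_ratio": config.one_day_ratio,
    }
    if model is not None:
        payload.update({
            "lambda": model.transform.lam,
            "offset": model.transform.offset,
            "sigma2_between": model.sigma2_between,
            "sigma2_within": model.sigma2_within,
            "converged": model.converged,
            "fit_method": model.method,
        })
    if extra:
        payload.update(extra)
    logger.info("run manifest: %s", payload)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
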