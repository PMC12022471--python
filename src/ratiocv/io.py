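"""File I/O and report assembly for the estimation pipeline.

Input is a delimited text extract with one row per result (columns
``patient_id, analyte, timestamp, value`` and optional ``sex, age``);
output is a per-subgroup report mirroring the standard presentation of
indirect CV_I results: number of ratios, long-term CV_A, Box-Cox(sigma)
with CI, indirect CV_I with CI, and the conversion scale used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_math import Scale
from .peak_fit import CvEstimate, FitConfig, bootstrap_ci, estimate_cvi
from .ratio_builder import (
    ResultRecord,
    build_consecutive_ratios,
    filter_records,
    sufficiency_check,
)

__all__ = [
    "InputError",
    "ParseResult",
    "RunConfig",
    "Report",
    "ReportRow",
    "read_results_csv",
    "run_estimate",
    "write_report",
    "REPORT_TSV_COLUMNS",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "analyte", "timestamp", "value")

#: TSV column order: subgroup identification, then the standard result
#: columns (number of ratios | long-term CV_A | Box-Cox(sigma) [CI] |
#: indirect CV_I [CI]), then diagnostics.
REPORT_TSV_COLUMNS = [
    "analyte", "subgroup", "n_ratios", "cv_a",
    "boxcox_sigma", "sigma_ci_low", "sigma_ci_high",
    "cv_i", "cv_i_ci_low", "cv_i_ci_high",
    "cv_total", "scale_used", "lambda", "n_boot_failed", "warnings",
    "boxcox_sigma_display", "cv_i_display",
]


class InputError(ValueError):
    """Fatal problem with the input file (missing file/column, empty data)."""


@dataclass
class ParseResult:
    """Validated input table plus parse diagnostics."""

    frame: pd.DataFrame
    n_read: int
    n_dropped: int
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[ResultRecord]:
        """Materialize rows as `ResultRecord` objects (convenience for small data)."""
        return [
            ResultRecord(patient_id=str(r.patient_id), analyte=str(r.analyte),
                         timestamp=r.timestamp, value=float(r.value),
                         sex=None if pd.isna(r.sex) else str(r.sex),
                         age=None if pd.isna(r.age) else float(r.age))
            for r in self.frame.itertuples(index=False)
        ]


def read_results_csv(path, delimiter: Optional[str] = None) -> ParseResult:
    """Read and validate a results extract (CSV, or TSV for ``.tsv`` files).

    Rows failing validation (non-positive or non-numeric value, unparseable
    timestamp, empty patient id) are dropped with a counted warning; a
    missing required column or an empty file is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise InputError(f"missing required column {col!r} in {path}")
    if df.empty:
        raise InputError(f"input file {path} contains a header but no data rows")
    for col in ("sex", "age"):
        if col not in df.columns:
            df[col] = pd.NA

    n_read = len(df)
    warnings_list: list[str] = []

    value = pd.to_numeric(df["value"], errors="coerce")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    ok = value.notna() & (value > 0) & np.isfinite(value.fillna(np.nan)) \
        & ts.notna() & df["patient_id"].notna() & (df["patient_id"].astype(str) != "")

    n_bad = int((~ok).sum())
    if n_bad:
        warnings_list.append(f"dropped {n_bad} invalid rows "
                             "(non-positive/non-numeric value, bad timestamp, or empty patient id)")
        logger.warning("%s: %s", path, warnings_list[-1])
    out = df.loc[ok, ["patient_id", "analyte", "timestamp", "value", "sex", "age"]].copy()
    out["value"] = value[ok]
    out["timestamp"] = ts[ok]
    return ParseResult(frame=out.reset_index(drop=True), n_read=n_read,
                       n_dropped=n_bad, warnings=warnings_list)


@dataclass(frozen=True)
class RunConfig:
    """Everything one estimation run needs."""

    input_path: str
    analyte: str
    cv_a: float = 0.0
    sex_filter: Optional[str] = None
    age_range: Optional[tuple[float, float]] = (18.0, 110.0)
    scale_override: Optional[Scale] = None
    n_boot: int = 0
    seed: int = 0
    min_ratios: int = 500
    disjoint_pairs: bool = False
    min_gap: Optional[str] = None  # pandas-parseable duration, e.g. "1D"
    max_gap: Optional[str] = None
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if self.cv_a < 0:
            raise ValueError("cv_a must be >= 0")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0 (0 = point estimate only)")


@dataclass
class ReportRow:
    """One analyte/subgroup line of the report."""

    analyte: str
    subgroup: str
    n_ratios: int
    cv_a: float
    boxcox_sigma: float
    cv_total: float
    cv_i: float
    scale_used: str
    lam: float
    sigma_ci: Optional[tuple[float, float]] = None
    cv_i_ci: Optional[tuple[float, float]] = None
    n_boot_failed: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class Report:
    """Estimation report: one row per analyte/subgroup plus run metadata."""

    rows: list[ReportRow]
    seed: int
    input_path: str = ""

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "analyte": r.analyte,
                "subgroup": r.subgroup,
                "n_ratios": r.n_ratios,
                "cv_a": r.cv_a,
                "boxcox_sigma": r.boxcox_sigma,
                "sigma_ci_low": r.sigma_ci[0] if r.sigma_ci else None,
                "sigma_ci_high": r.sigma_ci[1] if r.sigma_ci else None,
                "cv_i": r.cv_i,
                "cv_i_ci_low": r.cv_i_ci[0] if r.cv_i_ci else None,
                "cv_i_ci_high": r.cv_i_ci[1] if r.cv_i_ci else None,
                "cv_total": r.cv_total,
                "scale_used": r.scale_used,
                "lambda": r.lam,
                "n_boot_failed": r.n_boot_failed,
                "warnings": "; ".join(r.warnings),
                # display fields: banker's rounding to the customary precision
                "boxcox_sigma_display": f"{round(r.boxcox_sigma, 3):.3f}",
                "cv_i_display": f"{round(r.cv_i, 1):.1f}",
            })
        return pd.DataFrame.from_records(recs, columns=REPORT_TSV_COLUMNS)


def _subgroup_label(cfg: RunConfig) -> str:
    parts = []
    if cfg.sex_filter:
        parts.append({"F": "Female", "M": "Male"}.get(cfg.sex_filter, cfg.sex_filter))
    if cfg.age_range and tuple(cfg.age_range) != (18.0, 110.0):
        parts.append(f"age {cfg.age_range[0]:g}-{cfg.age_range[1]:g}")
    return " ".join(parts) if parts else "All"


def run_estimate(config: RunConfig) -> Report:
    """Full pipeline: read -> filter -> ratios -> fit (+bootstrap) -> report."""
    parsed = read_results_csv(config.input_path)
    logger.info("read %d rows (%d dropped) from %s",
                parsed.n_read, parsed.n_dropped, config.input_path)

    subset = filter_records(parsed.frame, config.analyte,
                            sex=config.sex_filter, age_range=config.age_range)
    if subset.empty:
        raise InputError(
            f"no records for analyte {config.analyte!r} in the requested subgroup")
    sample = build_consecutive_ratios(
        subset,
        min_gap=pd.Timedelta(config.min_gap) if config.min_gap else None,
        max_gap=pd.Timedelta(config.max_gap) if config.max_gap else None,
        disjoint_pairs=config.disjoint_pairs,
        subgroup=_subgroup_label(config),
    )
    warnings_list = sufficiency_check(sample)
    logger.info("%d ratios from %d patients", sample.n_ratios, sample.n_patients)

    fit_cfg = dataclasses.replace(config.fit, seed=config.seed,
                                  min_ratios=config.min_ratios)
    est: CvEstimate
    if config.n_boot > 0:
        est = bootstrap_ci(sample.ratios, fit_cfg, n_boot=config.n_boot,
                           cv_a=config.cv_a, seed=config.seed,
                           scale_override=config.scale_override)
        if est.ci_unreliable:
            warnings_list.append(
                f"bootstrap CI unreliable: {est.n_boot_failed}/{est.n_boot} replicates failed")
    else:
        est = estimate_cvi(sample.ratios, config.cv_a, fit_cfg,
                           scale_override=config.scale_override)
    logger.info("lambda=%.2f scale=%s cv_total=%.2f cv_i=%.2f (seed %d)",
                est.fit.lam, est.scale_used, est.cv_total, est.cv_i, config.seed)

    row = ReportRow(
        analyte=config.analyte, subgroup=sample.subgroup,
        n_ratios=sample.n_ratios, cv_a=config.cv_a,
        boxcox_sigma=est.fit.sigma_t, cv_total=est.cv_total, cv_i=est.cv_i,
        scale_used=est.scale_used, lam=est.fit.lam,
        sigma_ci=est.ci_sigma, cv_i_ci=est.ci_cv_i,
        n_boot_failed=est.n_boot_failed, warnings=warnings_list,
    )
    return Report(rows=[row], seed=config.seed, input_path=str(config.input_path))


def write_report(report: Report, path, format: str = "tsv") -> None:
    """Write the report as TSV (standard column order) or JSON (full detail)."""
    path = Path(path)
    try:
        if format == "tsv":
            report.to_frame().to_csv(path, sep="\t", index=False)
        elif format == "json":
            payload = {
                "seed": report.seed,
                "input_path": report.input_path,
                "rows": [dataclasses.asdict(r) for r in report.rows],
            }
            path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
        else:
            raise ValueError(f"unknown report format {format!r}")
    except OSError as exc:
        raise InputError(f"cannot write report to {path}: {exc}") from exc
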