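"""From raw laboratory result tables to consecutive-result ratio samples.

Each patient's results for one analyte, sorted in time, yield the ratios
of adjacent pairs (later result over earlier).  Subgroup filters (analyte,
sex, age) and data-sufficiency warnings live here; robustness to
pathological ratios is the peak fitter's job, so no outlier exclusion is
performed before ratio formation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ResultRecord",
    "RatioSample",
    "filter_records",
    "build_consecutive_ratios",
    "sufficiency_check",
    "MIN_RECOMMENDED_RATIOS",
    "MAX_RECOMMENDED_PATHOLOGICAL_FRACTION",
]

logger = logging.getLogger(__name__)

#: Recommended minimum number of ratios for a robust indirect CV_I estimate.
MIN_RECOMMENDED_RATIOS = 5000
#: Recommended upper bound on the pathological fraction.
MAX_RECOMMENDED_PATHOLOGICAL_FRACTION = 0.30

DEFAULT_AGE_RANGE = (18.0, 110.0)


@dataclass(frozen=True)
class ResultRecord:
    """One laboratory result: patient, analyte, time, positive value."""

    patient_id: str
    analyte: str
    timestamp: Union[str, np.datetime64, pd.Timestamp]
    value: float
    sex: Optional[str] = None  # 'F', 'M' or None/unknown
    age: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not (self.value > 0 and np.isfinite(self.value)):
            raise ValueError(f"result value must be positive and finite, got {self.value}")


@dataclass(frozen=True)
class RatioSample:
    """Consecutive-result ratios for one analyte/subgroup."""

    analyte: str
    subgroup: str
    ratios: np.ndarray
    n_patients: int
    n_ratios: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))
        if self.n_ratios != self.ratios.size:
            raise ValueError("n_ratios must equal len(ratios)")
        if self.ratios.size and not np.all(self.ratios > 0):
            raise ValueError("all ratios must be strictly positive")


def _to_frame(records: Union[pd.DataFrame, Iterable[ResultRecord]]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = list(records)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "analyte": [r.analyte for r in rows],
            "timestamp": [r.timestamp for r in rows],
            "value": [r.value for r in rows],
            "sex": [r.sex for r in rows],
            "age": [r.age for r in rows],
        }
    )


def filter_records(
    records: Union[pd.DataFrame, Sequence[ResultRecord]],
    analyte: str,
    sex: Optional[str] = None,
    age_range: Optional[tuple[float, float]] = DEFAULT_AGE_RANGE,
) -> pd.DataFrame:
    """Select one analyte and an optional sex/age subgroup (bounds inclusive).

    Records with unknown sex are excluded by a sex filter; records with
    missing age are excluded by an age filter.  An analyte absent from the
    data yields an empty frame plus a logged warning, not an exception.
    """
    df = _to_frame(records)
    out = df[df["analyte"] == analyte]
    if out.empty:
        logger.warning("no records found for analyte %r", analyte)
        return out.copy()
    if sex is not None and "sex" in out.columns:
        out = out[out["sex"] == sex]
    if age_range is not None and "age" in out.columns:
        age = pd.to_numeric(out["age"], errors="coerce")
        out = out[(age >= age_range[0]) & (age <= age_range[1])]
    return out.copy()


def build_consecutive_ratios(
    records: Union[pd.DataFrame, Sequence[ResultRecord]],
    min_gap: Optional[pd.Timedelta] = None,
    max_gap: Optional[pd.Timedelta] = None,
    disjoint_pairs: bool = False,
    subgroup: str = "All",
) -> RatioSample:
    """Per patient, sort by time and emit later/earlier ratios of adjacent pairs.

    Pairs overlap by default (k results give k-1 ratios); with
    ``disjoint_pairs`` each result is used at most once (floor(k/2) ratios).
    Pairs whose time gap falls outside [min_gap, max_gap] are dropped.
    Duplicate (patient, timestamp) rows are tie-broken by value ascending.
    """
    df = _to_frame(records)
    if df.empty:
        return RatioSample(analyte="", subgroup=subgroup,
                           ratios=np.empty(0), n_patients=0, n_ratios=0)
    analytes = df["analyte"].unique()
    if len(analytes) != 1:
        raise ValueError(f"records must contain exactly one analyte, got {list(analytes)}")

    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    n_dupes = int(df.duplicated(subset=["patient_id", "timestamp"]).sum())
    if n_dupes:
        logger.info("%d duplicate (patient, timestamp) rows; tie-broken by value", n_dupes)
    df = df.sort_values(["patient_id", "timestamp", "value"], kind="stable")

    same_patient = df["patient_id"].to_numpy()[1:] == df["patient_id"].to_numpy()[:-1]
    values = df["value"].to_numpy(dtype=float)
    gaps = df["timestamp"].to_numpy()[1:] - df["timestamp"].to_numpy()[:-1]
    keep = same_patient.copy()
    if min_gap is not None:
        keep &= gaps >= pd.Timedelta(min_gap).to_timedelta64()
    if max_gap is not None:
        keep &= gaps <= pd.Timedelta(max_gap).to_timedelta64()
    if disjoint_pairs:
        # greedy in time order: a pair consumes both results
        keep = keep.copy()
        prev_used = False
        for i in range(keep.size):
            if not same_patient[i]:
                prev_used = False
                continue
            if keep[i] and prev_used:
                keep[i] = False
            prev_used = keep[i]
    ratios = values[1:][keep] / values[:-1][keep]
    return RatioSample(
        analyte=str(analytes[0]),
        subgroup=subgroup,
        ratios=ratios,
        n_patients=int(df["patient_id"].nunique()),
        n_ratios=int(ratios.size),
    )


def sufficiency_check(
    sample: RatioSample,
    estimated_pathological_fraction: Optional[float] = None,
) -> list[str]:
    """Data-sufficiency warnings; advisory only, never blocks execution."""
    warnings_list: list[str] = []
    if sample.n_ratios < MIN_RECOMMENDED_RATIOS:
        warnings_list.append(
            f"only {sample.n_ratios} ratios; >= {MIN_RECOMMENDED_RATIOS} are "
            "recommended for a robust indirect CV_I estimate"
        )
    if (estimated_pathological_fraction is not None
            and estimated_pathological_fraction >= MAX_RECOMMENDED_PATHOLOGICAL_FRACTION):
        warnings_list.append(
            f"estimated pathological fraction {estimated_pathological_fraction:.0%} "
            f">= {MAX_RECOMMENDED_PATHOLOGICAL_FRACTION:.0%}; the central-peak fit "
            "may be contaminated"
        )
    for w in warnings_list:
        logger.warning("%s/%s: %s", sample.analyte, sample.subgroup, w)
    return warnings_list
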