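"""Monte Carlo generators and the validation harness for the ratio method.

Two kinds of synthetic data:

* ``simulate_ratio_sample`` draws pairs from a common Gaussian or lognormal
  parent and forms their ratios, optionally replacing a fraction with
  "pathological" ratios whose numerator is shifted by a multiplicative
  factor — the contamination the central-peak fit must resist.
* ``simulate_lis_dataset`` emulates a routine laboratory extract: each
  patient has a homeostatic set point drawn from a between-subject
  distribution, serial results scatter around it with within-subject
  (CV_I) and analytical (CV_A) variation, and a configurable fraction of
  patients undergo a sustained step shift or a monotone trend.

``run_monte_carlo_table`` wraps the first generator into the validation
grid (input CV vs. mean estimated CV over independent iterations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .core_math import ParentParams, Scale, sigma_for_target_lncv
from .peak_fit import FitConfig, fit_central_peak
from .core_math import cv_from_ratio_sigma, lncv_from_ratio_sigma
from .ratio_builder import RatioSample, ResultRecord

__all__ = [
    "SimulationSpec",
    "McTableRow",
    "simulate_ratio_sample",
    "run_monte_carlo_table",
    "simulate_lis_dataset",
]

#: Gaussian parent CV (%) beyond which truncation at zero materially
#: distorts the parent shape.
GAUSSIAN_CV_WARN = 33.0


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated ratio sample."""

    distribution: Scale = "gaussian"
    cv_percent: float = 10.0
    n_ratios: int = 1_000_000
    #: parent mean (analyte units) for gaussian; log-scale mean for lognormal.
    #: Ratios are scale-free, so the default only matters for truncation.
    mu: Optional[float] = None
    contamination_fraction: float = 0.0
    contamination_shift: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination_fraction < 1.0):
            raise ValueError("contamination_fraction must be in [0, 1)")
        if self.cv_percent <= 0:
            raise ValueError("cv_percent must be > 0")
        if self.n_ratios < 2:
            raise ValueError("n_ratios must be >= 2")

    @property
    def parent_mu(self) -> float:
        if self.mu is not None:
            return self.mu
        return 100.0 if self.distribution == "gaussian" else 0.0


def _draw_positive_normal(rng: np.random.Generator, mu: float, sd: float,
                          n: int) -> np.ndarray:
    """N(mu, sd) truncated to > 0 by redrawing (negligible mass for CV <= 20%)."""
    x = rng.normal(mu, sd, size=n)
    bad = x <= 0
    while np.any(bad):
        x[bad] = rng.normal(mu, sd, size=int(bad.sum()))
        bad = x <= 0
    return x


def simulate_ratio_sample(spec: SimulationSpec) -> RatioSample:
    """Draw i.i.d. parent pairs and return their ratio sample.

    Contaminated ratios have the numerator multiplied by
    ``contamination_shift`` or its reciprocal (50/50), emulating sustained
    pathological change between the two measurements.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_ratios
    if spec.distribution == "gaussian":
        if spec.cv_percent >= GAUSSIAN_CV_WARN:
            warnings.warn(
                f"gaussian parent CV {spec.cv_percent:g}% >= {GAUSSIAN_CV_WARN:g}%: "
                "truncation at zero materially distorts the parent distribution",
                stacklevel=2,
            )
        mu = spec.parent_mu
        sd = mu * spec.cv_percent / 100.0
        x1 = _draw_positive_normal(rng, mu, sd, n)
        x2 = _draw_positive_normal(rng, mu, sd, n)
    else:
        sigma_x = sigma_for_target_lncv(spec.cv_percent)
        x1 = np.exp(rng.normal(spec.parent_mu, sigma_x, size=n))
        x2 = np.exp(rng.normal(spec.parent_mu, sigma_x, size=n))

    ratios = x1 / x2
    if spec.contamination_fraction > 0:
        n_path = int(round(spec.contamination_fraction * n))
        idx = rng.choice(n, size=n_path, replace=False)
        shift = np.where(rng.random(n_path) < 0.5,
                         spec.contamination_shift, 1.0 / spec.contamination_shift)
        ratios[idx] *= shift

    return RatioSample(analyte="simulated", subgroup=str(spec.distribution),
                       ratios=ratios, n_patients=n, n_ratios=n)


@dataclass(frozen=True)
class McTableRow:
    """One validation-grid row: input CV vs. mean estimated CV."""

    distribution: Scale
    input_cv: float
    estimated_cv: float
    n_iterations: int
    n_failed: int = 0

    @property
    def flagged(self) -> bool:
        """True when more than 10% of iterations failed to fit."""
        return self.n_failed > 0.1 * (self.n_iterations + self.n_failed)


def run_monte_carlo_table(
    cv_grid_gaussian: Sequence[float] = tuple(np.arange(2.5, 20.01, 2.5)),
    cv_grid_lognormal: Sequence[float] = tuple(np.arange(5.0, 50.01, 5.0)),
    n_ratios: int = 1_000_000,
    n_iterations: int = 100,
    config: FitConfig | None = None,
    seed: int = 0,
) -> list[McTableRow]:
    """Validation grid: simulate, fit the central peak, average over iterations.

    Gaussian-parent rows are converted with the Gaussian formula and
    lognormal-parent rows with the lognormal formula, matching how each
    input CV was defined.  Full scale reproduces the published validation
    (1e6 ratios x 100 iterations); both knobs scale down for desk runs.
    """
    cfg = config or FitConfig()
    root = np.random.default_rng(seed)
    rows: list[McTableRow] = []
    grids: list[tuple[Scale, Sequence[float]]] = [
        ("gaussian", cv_grid_gaussian), ("lognormal", cv_grid_lognormal)]
    for dist, grid in grids:
        for cv in grid:
            estimates = []
            n_failed = 0
            for _ in range(n_iterations):
                it_seed = int(root.integers(0, 2**31 - 1))
                spec = SimulationSpec(distribution=dist, cv_percent=float(cv),
                                      n_ratios=n_ratios, seed=it_seed)
                sample = simulate_ratio_sample(spec)
                try:
                    fit = fit_central_peak(sample.ratios,
                                           replace(cfg, seed=it_seed))
                except ValueError:
                    n_failed += 1
                    continue
                if dist == "gaussian":
                    estimates.append(cv_from_ratio_sigma(fit.sigma_t))
                else:
                    estimates.append(lncv_from_ratio_sigma(fit.sigma_t))
            rows.append(McTableRow(distribution=dist, input_cv=float(cv),
                                   estimated_cv=float(np.mean(estimates)),
                                   n_iterations=len(estimates),
                                   n_failed=n_failed))
    return rows


DriftModel = Literal["step_shift", "trend"]


def simulate_lis_dataset(
    n_patients: int,
    results_per_patient,
    analyte: str,
    parent: ParentParams,
    cv_i: float,
    pathological_fraction: float = 0.0,
    drift_model: DriftModel = "step_shift",
    cv_a: float = 0.0,
    drift_magnitude: float = 1.5,
    mean_interval_days: float = 30.0,
    start: str = "2020-01-01",
    seed: int = 0,
) -> list[ResultRecord]:
    """Synthetic routine-laboratory extract with a pathological subpopulation.

    Healthy patients scatter multiplicatively around a personal set point
    drawn from ``parent`` (the between-subject distribution), with
    log-normal within-subject (``cv_i``, %) and analytical (``cv_a``, %)
    components.  A ``pathological_fraction`` of patients additionally get a
    sustained multiplicative ``step_shift`` after a random change point, or
    a monotone multiplicative ``trend`` across their series.  Visits are
    spaced by exponential inter-visit times (mean ``mean_interval_days``).

    ``results_per_patient`` may be an int (every patient) or a callable
    ``rng -> int`` drawing a count per patient.
    """
    if not (0.0 <= pathological_fraction <= 0.5):
        raise ValueError("pathological_fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    sigma_i = sigma_for_target_lncv(cv_i) if cv_i > 0 else 0.0
    sigma_a = sigma_for_target_lncv(cv_a) if cv_a > 0 else 0.0
    sigma_w = float(np.hypot(sigma_i, sigma_a))
    t0 = np.datetime64(start)

    records: list[ResultRecord] = []
    n_path = int(round(pathological_fraction * n_patients))
    for p in range(n_patients):
        if callable(results_per_patient):
            k = int(results_per_patient(rng))
        else:
            k = int(results_per_patient)
        if k < 1:
            continue
        if parent.scale_kind == "gaussian":
            setpoint = -1.0
            while setpoint <= 0:
                setpoint = rng.normal(parent.mu, parent.sigma)
        else:
            setpoint = float(np.exp(rng.normal(parent.mu, parent.sigma)))
        values = setpoint * np.exp(rng.normal(0.0, sigma_w, size=k))
        if p < n_path and k > 1:
            log_mag = np.log(drift_magnitude)
            if rng.random() < 0.5:
                log_mag = -log_mag
            if drift_model == "step_shift":
                change = rng.integers(1, k)
                shift = np.zeros(k)
                shift[change:] = log_mag
            else:  # trend: monotone drift reaching the full magnitude at the end
                shift = np.linspace(0.0, log_mag, k)
            values = values * np.exp(shift)
        gaps_days = rng.exponential(mean_interval_days, size=k)
        times = t0 + np.cumsum(np.maximum(gaps_days, 0.01) * 86400).astype("timedelta64[s]")
        sex = "F" if rng.random() < 0.5 else "M"
        age = float(rng.integers(18, 90))
        pid = f"P{p:06d}"
        for j in range(k):
            records.append(ResultRecord(patient_id=pid, analyte=analyte,
                                        timestamp=times[j], value=float(values[j]),
                                        sex=sex, age=age))
    return records
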