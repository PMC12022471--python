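"""Closed-form conversions between ratio-scale sigmas and CV percentages.

A pair of independent measurements :math:`X_1, X_2` from the same patient
defines the result ratio :math:`Z = X_1/X_2`.  For a near-Gaussian parent
``X ~ N(mu, sigma)`` the ratio is approximately ``N(1, sqrt(2)*sigma/mu)``,
so the total CV of a single measurement is recovered from the ratio-scale
standard deviation as

    CV_Total% = sigma_z / sqrt(2) * 100.                          (Gaussian)

For a lognormal parent ``ln X ~ N(mu, sigma_x)`` the log-ratio is exactly
``N(0, sqrt(2)*sigma_x)`` and the CV of X is

    ln-CV% = sqrt(exp(sigma_x^2) - 1) * 100,  sigma_x = sigma_z/sqrt(2).

Within-subject biological variation is then obtained by removing the
long-term analytical imprecision in quadrature:

    CV_I = sqrt(CV_Total^2 - CV_A^2).

All functions here are pure and operate on floats (or a `RatioSigma`
record); the estimation pipeline in :mod:`ratiocv.peak_fit` composes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
from scipy import special

__all__ = [
    "SQRT2",
    "Scale",
    "RatioSigma",
    "ParentParams",
    "AnalyticalNoiseError",
    "boxcox_transform",
    "cv_from_ratio_sigma",
    "lncv_from_ratio_sigma",
    "sigma_for_target_lncv",
    "subtract_cva",
    "choose_scale",
]

SQRT2 = math.sqrt(2.0)

#: Scale on which a ratio-sigma is converted to a CV percentage.
Scale = Literal["gaussian", "lognormal"]

#: Gaussian-path CV_Total (%) above which the Gaussian ratio approximation
#: degrades and the lognormal conversion is preferred by default.
DEFAULT_SCALE_THRESHOLD = 20.0


@dataclass(frozen=True)
class RatioSigma:
    """SD of (Box-Cox transformed) result ratios, with the exponent used."""

    sigma: float
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError(f"ratio sigma must be finite and > 0, got {self.sigma}")
        if not math.isfinite(self.lam):
            raise ValueError(f"Box-Cox lambda must be finite, got {self.lam}")


@dataclass(frozen=True)
class ParentParams:
    """Parameters of the parent result distribution.

    For ``scale_kind='gaussian'``, ``mu``/``sigma`` are in analyte units;
    for ``'lognormal'`` they are the log-scale mean and SD.
    """

    mu: float
    sigma: float
    scale_kind: Scale = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("parent sigma must be > 0")
        if self.scale_kind == "gaussian" and self.mu <= 0:
            raise ValueError("gaussian parent mean must be > 0")

    @property
    def cv_percent(self) -> float:
        """CV (%) of the parent distribution."""
        if self.scale_kind == "gaussian":
            return self.sigma / self.mu * 100.0
        return math.sqrt(math.expm1(self.sigma**2)) * 100.0


class AnalyticalNoiseError(ValueError):
    """Raised when CV_A >= CV_Total: analytical noise swamps the biological signal."""


def _sigma_of(s: Union[RatioSigma, float]) -> float:
    sigma = s.sigma if isinstance(s, RatioSigma) else float(s)
    if not (sigma > 0):
        raise ValueError(f"ratio sigma must be > 0, got {sigma}")
    return sigma


def boxcox_transform(z, lam: float):
    """Box-Cox power transform ``(z**lam - 1)/lam``, ``ln z`` at ``lam = 0``.

    Accepts scalars or arrays; ``z`` must be strictly positive.  The
    ``lam = 0`` branch is the exact logarithm, and the transform is
    continuous in ``lam`` at 0.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr <= 0) or not np.all(np.isfinite(z_arr)):
        bad = z_arr[~(z_arr > 0) | ~np.isfinite(z_arr)].ravel()
        raise ValueError(f"Box-Cox requires positive finite values; offending value {bad[0]!r}")
    out = special.boxcox(z_arr, lam)
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


def cv_from_ratio_sigma(s: Union[RatioSigma, float]) -> float:
    """Gaussian-path CV (%): ``sigma_z / sqrt(2) * 100``."""
    return _sigma_of(s) / SQRT2 * 100.0


def lncv_from_ratio_sigma(s: Union[RatioSigma, float]) -> float:
    """Lognormal-path CV (%): ``sqrt(exp((sigma_z/sqrt(2))**2) - 1) * 100``."""
    sigma_x = _sigma_of(s) / SQRT2
    var = sigma_x**2
    if var > 700.0:  # expm1 overflow threshold for float64
        raise OverflowError(f"ratio sigma {sigma_x * SQRT2:g} too large for the lognormal CV formula")
    return math.sqrt(math.expm1(var)) * 100.0


def sigma_for_target_lncv(cv: float) -> float:
    """Log-scale parent SD ``sigma_x`` whose lognormal CV equals ``cv`` (%).

    Inverse of :func:`lncv_from_ratio_sigma` up to the ``sqrt(2)`` ratio
    factor: ``lncv_from_ratio_sigma(sqrt(2) * sigma_for_target_lncv(cv)) == cv``.
    """
    if not cv > 0:
        raise ValueError(f"target CV must be > 0, got {cv}")
    return math.sqrt(math.log1p((cv / 100.0) ** 2))


def subtract_cva(cv_total: float, cv_a: float) -> float:
    """Indirect CV_I (%) by quadrature: ``sqrt(cv_total**2 - cv_a**2)``."""
    if cv_a < 0:
        raise ValueError(f"CV_A must be >= 0, got {cv_a}")
    if cv_a >= cv_total:
        raise AnalyticalNoiseError(
            f"CV_A ({cv_a:g}%) >= CV_Total ({cv_total:g}%): analytical variation "
            "swamps the biological signal; indirect CV_I is undefined"
        )
    return math.sqrt(cv_total**2 - cv_a**2)


def choose_scale(cv_total_gaussian: float, threshold: float = DEFAULT_SCALE_THRESHOLD) -> Scale:
    """Pick the conversion scale from the Gaussian-path CV_Total estimate.

    The Gaussian ratio approximation is accurate for CVs up to ~15% and
    usable to ~20%; above the threshold the lognormal formula is used.
    A value exactly at the threshold keeps the Gaussian scale.
    """
    return "lognormal" if cv_total_gaussian > threshold else "gaussian"
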