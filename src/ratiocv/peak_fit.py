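"""Robust estimation of the central Box-Cox-normal peak of a ratio distribution.

Routine laboratory data mix a dominant peak of non-pathological ratios
(random biological + analytical variation, centred at 1) with pathological
or otherwise non-random changes that contaminate both tails.  The estimator
here recovers the central peak's parameters (lambda, mu_t, sigma_t):

1. For each Box-Cox exponent ``lambda`` on a two-stage grid, transform the
   ratios and locate the mode of the transformed density by a smoothed
   histogram.
2. Fit a truncated normal by maximum likelihood to the central quantile
   window around the mode, then re-centre the window at
   ``mu_t +/- k * sigma_t`` and refit to a fixed point, so the fit tracks
   the uncontaminated core rather than the tails.
3. Score each ``lambda`` by a reduced chi-square between the fitted
   truncated normal and the observed histogram over the core bins,
   penalised when the core collapses to a small fraction of the sample;
   the best-scoring ``lambda`` wins.

``sigma_t`` then converts to CV_Total via the Gaussian or lognormal formula
(:mod:`ratiocv.core_math`) and to the indirect CV_I by quadrature
subtraction of CV_A.  Percentile bootstrap CIs come from case resampling of
the ratios with a full refit per replicate.

Truncated-normal ML exploits that the family (fixed support) is a
two-parameter exponential family: the MLE matches the truncated mean and
variance, solved by fixed-point iteration on running sums, so each window
evaluation costs O(log n) after one sort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr  # standard normal CDF, scalar-fast

from .core_math import (
    SQRT2,
    AnalyticalNoiseError,
    Scale,
    choose_scale,
    cv_from_ratio_sigma,
    lncv_from_ratio_sigma,
    subtract_cva,
)

__all__ = [
    "FitConfig",
    "PeakFit",
    "CvEstimate",
    "fit_central_peak",
    "profile_ml_boxcox_fit",
    "estimate_cvi",
    "bootstrap_ci",
]

_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the central-peak estimator.

    The defaults are chosen for ratio samples centred near 1 with up to
    ~30% contamination; see docs/methods.md for the rationale of each.
    """

    lambda_min: float = -2.0
    lambda_max: float = 2.0
    coarse_step: float = 0.1
    fine_step: float = 0.01
    #: proportion of the sample initially treated as the uncontaminated core
    central_span: float = 0.8
    #: span used instead when fewer than `widen_below` points fall in the core
    widen_span: float = 0.9
    widen_below: int = 1000
    #: half-width (in fitted SDs) of the re-centred window used to score
    #: normality when selecting lambda; wide enough to discriminate shapes
    select_k: float = 1.8
    #: half-width (in fitted SDs) of the final window the sigma estimate is
    #: fitted on; narrow enough to shed pathological shoulders
    sigma_k: float = 1.3
    max_recenter: int = 10
    #: minimum histogram bins for the chi-square score
    min_bins: int = 50
    #: lambda-grid search runs on a subsample of at most this many ratios
    max_grid_n: int = 200_000
    min_ratios: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.central_span <= 1.0):
            raise ValueError("central_span must be in (0, 1]")
        if self.lambda_max < self.lambda_min:
            raise ValueError("empty lambda grid")

    @property
    def lambda_grid(self) -> np.ndarray:
        """Coarse lambda grid (the fine stage refines around the best value)."""
        n = int(round((self.lambda_max - self.lambda_min) / self.coarse_step)) + 1
        return self.lambda_min + self.coarse_step * np.arange(n)


@dataclass(frozen=True)
class PeakFit:
    """Fitted central Box-Cox-normal peak on the transformed scale."""

    lam: float
    mu_t: float
    sigma_t: float
    score: float
    n_used: int
    n_ratios: int
    diagnostics: tuple = field(default=(), repr=False)  # (lambda, score, sigma) trace

    def __post_init__(self) -> None:
        if not (self.sigma_t > 0 and math.isfinite(self.sigma_t)):
            raise ValueError(f"fitted sigma must be finite and > 0, got {self.sigma_t}")


@dataclass(frozen=True)
class CvEstimate:
    """CV_Total and indirect CV_I (%), with the conversion scale and CIs."""

    cv_total: float
    cv_i: float
    scale_used: Scale
    n_ratios: int
    cv_a: float
    fit: PeakFit
    ci_sigma: Optional[tuple[float, float]] = None
    ci_cv_i: Optional[tuple[float, float]] = None
    n_boot: int = 0
    n_boot_failed: int = 0
    ci_unreliable: bool = False


# ---------------------------------------------------------------------------
# low-level numerics
# ---------------------------------------------------------------------------

def _phi(x: float) -> float:
    return _INV_SQRT_2PI * math.exp(-0.5 * x * x)


def _std_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x * 0.7071067811865476))


def _moment_step(m: float, v: float, a: float, b: float,
                 mu: float, sigma: float) -> tuple[float, float]:
    """One moment-matching update toward the truncated-normal MLE.

    For fixed support the truncated normal is a two-parameter exponential
    family, so the MLE matches the first two truncated moments; this is one
    step of the corresponding fixed-point iteration.
    """
    alpha = (a - mu) / sigma
    beta = (b - mu) / sigma
    z = _std_cdf(beta) - _std_cdf(alpha)
    if z < 1e-12:
        return mu, sigma
    pa, pb = _phi(alpha), _phi(beta)
    r = (pa - pb) / z
    var_factor = 1.0 + (alpha * pa - beta * pb) / z - r * r
    if var_factor < 0.02:  # pathologically wide window relative to sigma
        var_factor = 0.02
    sigma_new = math.sqrt(v / var_factor)
    mu_new = m - sigma_new * r
    return mu_new, sigma_new


def _aitken(x0: float, x1: float, x2: float) -> float:
    """Aitken delta-squared extrapolation of a linearly converging sequence."""
    d = x2 - 2.0 * x1 + x0
    if abs(d) < 1e-300:
        return x2
    acc = x2 - (x2 - x1) ** 2 / d
    return acc if math.isfinite(acc) else x2


def _aitken_pair(hist: list[tuple[float, float]],
                 mu_new: float, sigma_new: float) -> tuple[float, float]:
    """Joint Aitken step for (mu, sigma), rejected when implausible (the
    early window-moving iterations are not yet in the linear regime)."""
    mu_acc = _aitken(hist[0][0], hist[1][0], hist[2][0])
    sig_acc = _aitken(hist[0][1], hist[1][1], hist[2][1])
    if (0.5 * sigma_new < sig_acc < 2.0 * sigma_new
            and abs(mu_acc - mu_new) < 2.0 * sigma_new):
        return mu_acc, sig_acc
    return mu_new, sigma_new


def _truncnorm_mle(m: float, v: float, a: float, b: float,
                   mu0: float, sigma0: float, tol: float = 1e-9) -> tuple[float, float]:
    """Truncated-normal MLE on fixed support [a, b] from core mean/variance.

    Fixed-point iteration on the moment equations with Aitken acceleration
    every third step (the plain iteration converges only linearly).
    """
    mu, sigma = mu0, max(sigma0, 1e-12)
    hist: list[tuple[float, float]] = []
    for it in range(60):
        mu_new, sigma_new = _moment_step(m, v, a, b, mu, sigma)
        hist.append((mu_new, sigma_new))
        if len(hist) == 3:
            mu_new, sigma_new = _aitken_pair(hist, mu_new, sigma_new)
            hist.clear()
        done = (abs(sigma_new - sigma) < tol * sigma
                and abs(mu_new - mu) < tol * sigma)
        mu, sigma = mu_new, sigma_new
        if done:
            break
    return mu, sigma


class _SortedSample:
    """Sorted transformed sample with prefix sums for O(log n) window stats."""

    __slots__ = ("t", "cum1", "cum2", "n")

    def __init__(self, t_sorted: np.ndarray):
        self.t = t_sorted
        self.n = t_sorted.size
        self.cum1 = np.concatenate(([0.0], np.cumsum(t_sorted)))
        self.cum2 = np.concatenate(([0.0], np.cumsum(t_sorted * t_sorted)))

    def window(self, a: float, b: float) -> tuple[int, int]:
        i0 = int(np.searchsorted(self.t, a, side="left"))
        i1 = int(np.searchsorted(self.t, b, side="right"))
        return i0, i1

    def moments(self, i0: int, i1: int) -> tuple[int, float, float]:
        n = i1 - i0
        s1 = self.cum1[i1] - self.cum1[i0]
        s2 = self.cum2[i1] - self.cum2[i0]
        m = s1 / n
        v = max(s2 / n - m * m, 0.0)
        return n, m, v


def _locate_mode(s: _SortedSample) -> float:
    """Mode of the transformed density from a smoothed histogram."""
    n = s.n
    lo = s.t[max(int(0.005 * n), 0)]
    hi = s.t[min(int(0.995 * n), n - 1)]
    if hi <= lo:
        raise ValueError("degenerate ratio sample: zero variance in the central 99%")
    nb = int(min(max(math.sqrt(n), 30), 400))
    edges = np.linspace(lo, hi, nb + 1)
    counts = np.diff(np.searchsorted(s.t, edges)).astype(float)
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smooth = np.convolve(counts, kernel / kernel.sum(), mode="same")
    k = int(np.argmax(smooth))
    return 0.5 * (edges[k] + edges[k + 1])


def _recenter(s: _SortedSample, mu: float, sigma: float, k: float,
              max_iter: int, i0: int, i1: int) -> tuple[float, float, int, int]:
    """Truncated ML with the window re-centred at mu +/- k*sigma.

    Window placement and the moment fixed-point share one loop (each
    iteration moves the window and takes one ML step), with Aitken
    acceleration on the jointly converging sequence; a full MLE polish at
    the final window finishes the fit.
    """
    hist: list[tuple[float, float]] = []
    a = b = None
    m = v = 0.0
    for _ in range(12 * max_iter):
        a, b = mu - k * sigma, mu + k * sigma
        j0, j1 = s.window(a, b)
        if j1 - j0 < 50:
            break
        _, m, v = s.moments(j0, j1)
        if v <= 0:
            break
        i0, i1 = j0, j1
        mu_new, sigma_new = _moment_step(m, v, a, b, mu, sigma)
        hist.append((mu_new, sigma_new))
        if len(hist) == 3:
            mu_new, sigma_new = _aitken_pair(hist, mu_new, sigma_new)
            hist.clear()
        converged = (abs(sigma_new - sigma) < 1e-7 * sigma
                     and abs(mu_new - mu) < 1e-7 * sigma)
        mu, sigma = mu_new, sigma_new
        if converged:
            break
    if a is not None and i1 - i0 >= 50 and v > 0:
        mu, sigma = _truncnorm_mle(m, v, a, b, mu, sigma)
    return mu, sigma, i0, i1


def _core_fit(s: _SortedSample, cfg: FitConfig, k: float) -> tuple[float, float, int, int]:
    """Truncated-ML fit of the central peak; returns (mu, sigma, i0, i1).

    Starts from the central quantile band around the mode, then re-centres
    the window at ``mu +/- k*sigma`` so tail contamination included by the
    initial band is shed.
    """
    mode = _locate_mode(s)
    n = s.n
    p_mode = np.searchsorted(s.t, mode) / n

    span = cfg.central_span
    for attempt in (0, 1):
        half = span / 2.0
        plo = min(max(p_mode - half, 0.0), 1.0 - span)
        i0 = int(plo * n)
        i1 = min(i0 + int(span * n), n)
        if i1 - i0 >= cfg.widen_below or attempt == 1 or span >= cfg.widen_span:
            break
        span = cfg.widen_span

    n_core, m, v = s.moments(i0, i1)
    if v <= 0:
        raise ValueError("degenerate ratio sample: zero variance in the core window")
    a, b = s.t[i0], s.t[i1 - 1]
    mu, sigma = _truncnorm_mle(m, v, a, b, m, math.sqrt(v))
    return _recenter(s, mu, sigma, k, cfg.max_recenter, i0, i1)


def _chi2_score(s: _SortedSample, mu: float, sigma: float,
                i0: int, i1: int, cfg: FitConfig) -> float:
    """Reduced chi-square of the truncated-normal fit over the core bins,
    penalised when the core holds an implausibly small share of the data."""
    n_core = i1 - i0
    if n_core < 10 or i0 < 0 or i1 > s.n:
        return math.inf
    a, b = s.t[i0], s.t[i1 - 1]
    if b <= a:
        return math.inf
    q75 = s.t[i0 + int(0.75 * n_core)]
    q25 = s.t[i0 + int(0.25 * n_core)]
    iqr = q75 - q25
    if iqr <= 0:
        return math.inf
    h = 2.0 * iqr / n_core ** (1.0 / 3.0)  # Freedman-Diaconis
    nb = int(min(max(math.ceil((b - a) / h), cfg.min_bins), 2000))
    edges = np.linspace(a, b, nb + 1)
    idx = np.searchsorted(s.t, edges, side="left")
    idx[0], idx[-1] = i0, i1  # window bounds inclusive of both edge points
    obs = np.diff(idx).astype(float)
    cdf = ndtr((edges - mu) / sigma)
    denom = cdf[-1] - cdf[0]
    if denom <= 0:
        return math.inf
    exp_counts = n_core * np.diff(cdf) / denom
    mask = exp_counts > 1e-9
    chi2 = float(np.sum((obs[mask] - exp_counts[mask]) ** 2 / exp_counts[mask]))
    dof = max(int(mask.sum()) - 3, 1)
    score = chi2 / dof
    # penalty: a core much smaller than the configured span signals a
    # degenerate transform that isolated a spike rather than the peak
    expected = 0.5 * cfg.central_span * s.n
    if n_core < expected:
        score += math.log(expected / n_core)
    return score


def _transform_sorted(logz_sorted: np.ndarray, lam: float) -> np.ndarray:
    # Box-Cox is monotone increasing in z for every lambda, so transforming
    # the sorted log-ratios preserves order: one sort serves the whole grid.
    if lam == 0.0:
        return logz_sorted
    return np.expm1(lam * logz_sorted) / lam


def _fit_at_lambda(logz_sorted: np.ndarray, lam: float, cfg: FitConfig,
                   final: bool = False) -> tuple[float, float, float, int]:
    """Fit one exponent.  Selection passes (``final=False``) score normality
    on the wide window; the final pass narrows the window to ``sigma_k``
    fitted SDs for the contamination-robust sigma estimate."""
    s = _SortedSample(_transform_sorted(logz_sorted, lam))
    mu, sigma, i0, i1 = _core_fit(s, cfg, cfg.select_k)
    if final:
        mu, sigma, i0, i1 = _recenter(s, mu, sigma, cfg.sigma_k,
                                      cfg.max_recenter, i0, i1)
    score = _chi2_score(s, mu, sigma, i0, i1, cfg)
    return mu, sigma, score, i1 - i0


def _validate_ratios(ratios, min_ratios: int) -> np.ndarray:
    z = np.asarray(ratios, dtype=float).ravel()
    if z.size < min_ratios:
        raise ValueError(f"need at least {min_ratios} ratios, got {z.size}")
    if np.any(~np.isfinite(z)) or np.any(z <= 0):
        raise ValueError("ratios must be positive and finite")
    if np.all(z == z[0]):
        raise ValueError("degenerate ratio sample: zero variance (all ratios equal)")
    return z


def _best_lambda(scores: Sequence[tuple[float, float]], tol: float = 1e-9) -> float:
    """Among (lambda, score) pairs, lowest score; ties toward 1 then 0."""
    best = min(sc for _, sc in scores)
    tied = [lam for lam, sc in scores if sc <= best + tol]
    return min(tied, key=lambda lam: (abs(lam - 1.0), abs(lam)))


def fit_central_peak(ratios, config: FitConfig | None = None) -> PeakFit:
    """Fit the central Box-Cox-normal peak of a ratio sample.

    Two-stage grid search over the Box-Cox exponent (coarse 0.1 steps on
    [lambda_min, lambda_max], then 0.01 steps around the coarse optimum);
    at each exponent a truncated-ML core fit with chi-square scoring, as
    described in the module docstring.  Deterministic given ``config.seed``
    (randomness enters only through the optional grid-search subsample).
    """
    cfg = config or FitConfig()
    z = _validate_ratios(ratios, cfg.min_ratios)
    logz_full = np.sort(np.log(z), kind="stable")

    if logz_full.size > cfg.max_grid_n:
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(logz_full.size, size=cfg.max_grid_n, replace=False)
        logz_grid = logz_full[np.sort(idx)]
    else:
        logz_grid = logz_full

    trace: list[tuple[float, float, float]] = []
    coarse: list[tuple[float, float]] = []
    for lam in cfg.lambda_grid:
        lam = round(float(lam), 10)
        try:
            _, sigma, score, _ = _fit_at_lambda(logz_grid, lam, cfg)
        except ValueError:
            continue
        coarse.append((lam, score))
        trace.append((lam, score, sigma))
    if not coarse:
        raise ValueError("no Box-Cox exponent produced a valid central-peak fit")

    lam0 = _best_lambda(coarse)
    fine: list[tuple[float, float]] = [c for c in coarse if abs(c[0] - lam0) < 1e-9]
    n_fine = int(round(cfg.coarse_step / cfg.fine_step)) - 1
    for k in range(-n_fine, n_fine + 1):
        lam = round(lam0 + k * cfg.fine_step, 10)
        if k == 0 or lam < cfg.lambda_min or lam > cfg.lambda_max:
            continue
        try:
            _, sigma, score, _ = _fit_at_lambda(logz_grid, lam, cfg)
        except ValueError:
            continue
        fine.append((lam, score))
        trace.append((lam, score, sigma))

    lam_best = _best_lambda(fine)
    # final fit at the chosen exponent always uses the full sample
    mu, sigma, score, n_used = _fit_at_lambda(logz_full, lam_best, cfg, final=True)
    return PeakFit(lam=lam_best, mu_t=mu, sigma_t=sigma, score=score,
                   n_used=n_used, n_ratios=logz_full.size,
                   diagnostics=tuple(sorted(trace)))


def profile_ml_boxcox_fit(ratios, lambda_grid=None,
                          config: FitConfig | None = None) -> PeakFit:
    """Full-sample profile-ML Box-Cox fit (clean-data reference estimator).

    For each exponent the profile log-likelihood is the Gaussian ML of the
    transformed sample plus the Box-Cox Jacobian term
    ``(lambda - 1) * sum(log z)``; no contamination handling.  Serves as the
    independent oracle that :func:`fit_central_peak` must match on
    uncontaminated samples.
    """
    cfg = config or FitConfig()
    z = _validate_ratios(ratios, cfg.min_ratios)
    logz = np.log(z)
    n = logz.size
    jac = float(np.sum(logz))

    def neg_profile_ll(lam: float) -> tuple[float, float, float]:
        t = logz if lam == 0.0 else np.expm1(lam * logz) / lam
        m = float(np.mean(t))
        v = float(np.var(t))
        if v <= 0:
            return math.inf, m, 0.0
        ll = -0.5 * n * math.log(v) + (lam - 1.0) * jac
        return -ll, m, math.sqrt(v)

    if lambda_grid is None:
        grid = cfg.lambda_grid
    else:
        grid = np.asarray(lambda_grid, dtype=float)

    trace = []
    coarse = []
    for lam in grid:
        lam = round(float(lam), 10)
        nll, m, sd = neg_profile_ll(lam)
        coarse.append((lam, nll))
        trace.append((lam, nll, sd))
    lam0 = _best_lambda(coarse)
    fine = [c for c in coarse if abs(c[0] - lam0) < 1e-9]
    if lambda_grid is None:
        n_fine = int(round(cfg.coarse_step / cfg.fine_step)) - 1
        for k in range(-n_fine, n_fine + 1):
            lam = round(lam0 + k * cfg.fine_step, 10)
            if k == 0 or lam < cfg.lambda_min or lam > cfg.lambda_max:
                continue
            nll, m, sd = neg_profile_ll(lam)
            fine.append((lam, nll))
            trace.append((lam, nll, sd))
    lam_best = _best_lambda(fine)
    nll, m, sd = neg_profile_ll(lam_best)
    if sd <= 0:
        raise ValueError("degenerate ratio sample: zero variance after transform")
    return PeakFit(lam=lam_best, mu_t=m, sigma_t=sd, score=nll,
                   n_used=n, n_ratios=n, diagnostics=tuple(sorted(trace)))


# ---------------------------------------------------------------------------
# CV pipeline
# ---------------------------------------------------------------------------

def _cv_from_fit(fit: PeakFit, cv_a: float,
                 scale_override: Optional[Scale]) -> tuple[float, float, Scale]:
    cv_gauss = cv_from_ratio_sigma(fit.sigma_t)
    scale: Scale = scale_override or choose_scale(cv_gauss)
    cv_total = cv_gauss if scale == "gaussian" else lncv_from_ratio_sigma(fit.sigma_t)
    cv_i = subtract_cva(cv_total, cv_a) if cv_a > 0 else cv_total
    return cv_total, cv_i, scale


def estimate_cvi(ratios, cv_a: float, config: FitConfig | None = None,
                 scale_override: Optional[Scale] = None) -> CvEstimate:
    """Point estimate of the indirect within-subject CV.

    Composes the central-peak fit, the Gaussian/lognormal scale choice
    (automatic above 20% CV_Total unless overridden) and the quadrature
    subtraction of the analytical CV.  Raises
    :class:`~ratiocv.core_math.AnalyticalNoiseError` when CV_A >= CV_Total.
    """
    fit = fit_central_peak(ratios, config)
    cv_total, cv_i, scale = _cv_from_fit(fit, cv_a, scale_override)
    return CvEstimate(cv_total=cv_total, cv_i=cv_i, scale_used=scale,
                      n_ratios=fit.n_ratios, cv_a=cv_a, fit=fit)


def bootstrap_ci(ratios, config: FitConfig | None = None, n_boot: int = 1000,
                 cv_a: float = 0.0, seed: int = 0,
                 scale_override: Optional[Scale] = None) -> CvEstimate:
    """Percentile bootstrap CIs for sigma_t and the indirect CV_I.

    Nonparametric case resampling of the ratios; each replicate is refit
    with :func:`fit_central_peak` and pushed through the same conversion
    scale as the full-sample point estimate.  Replicates where CV_A exceeds
    the replicate's CV_Total are counted as failures; the interval is
    flagged unreliable when more than 10% fail.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cfg = config or FitConfig()
    point = estimate_cvi(ratios, cv_a, cfg, scale_override)

    z_sorted = np.sort(np.asarray(ratios, dtype=float).ravel())
    n = z_sorted.size
    rng = np.random.default_rng(seed)
    p = np.full(n, 1.0 / n)

    sigmas, cvis = [], []
    n_failed = 0
    for b in range(n_boot):
        counts = rng.multinomial(n, p)
        rep = np.repeat(z_sorted, counts)  # already sorted
        rep_cfg = replace(cfg, seed=int(rng.integers(0, 2**31 - 1)))
        try:
            fit = fit_central_peak(rep, rep_cfg)
            _, cv_i, _ = _cv_from_fit(fit, cv_a, point.scale_used)
        except (ValueError, AnalyticalNoiseError, OverflowError):
            n_failed += 1
            continue
        sigmas.append(fit.sigma_t)
        cvis.append(cv_i)

    if not sigmas:
        raise RuntimeError("all bootstrap replicates failed")
    ci_sigma = tuple(np.percentile(sigmas, [2.5, 97.5]))
    ci_cvi = tuple(np.percentile(cvis, [2.5, 97.5]))
    return CvEstimate(cv_total=point.cv_total, cv_i=point.cv_i,
                      scale_used=point.scale_used, n_ratios=n, cv_a=cv_a,
                      fit=point.fit, ci_sigma=ci_sigma, ci_cv_i=ci_cvi,
                      n_boot=n_boot, n_boot_failed=n_failed,
                      ci_unreliable=n_failed > 0.1 * n_boot)
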