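# Methods

## The model

`ratiocv` estimates within-subject biological variation (CV_I) from
routine laboratory data without a dedicated sampling study.  The raw
material is the **result ratio**: for each patient with serial results of
one analyte, the quotient of each chronologically adjacent pair,
Z = X₂/X₁.  If the two results differ only by random within-subject and
analytical variation, Z scatters around 1; genuine clinical change pushes
ratios away from 1 and contaminates the tails.  The method therefore
estimates the spread of the *central peak* of the ratio distribution and
converts it to a CV:

* **Gaussian parent** X ~ N(μ, σ): the ratio is approximately
  N(1, √2·σ/μ), so `CV_Total% = σ_z/√2 × 100`.
* **Lognormal parent** ln X ~ N(μ, σ_x): ln Z is exactly
  N(0, √2·σ_x), so with σ_x = σ_z/√2,
  `ln-CV% = √(exp(σ_x²) − 1) × 100`.

Skewed ratio distributions are first made approximately Gaussian by a
Box-Cox transform ((z^λ−1)/λ; ln z at λ = 0); σ_z above is then the SD of
the transformed central peak.  Because the transform has unit derivative
at z = 1, the transformed SD remains interpretable on the ratio scale.

CV_Total combines within-subject and analytical variation in quadrature,
so the final step removes the long-term analytical CV measured on quality
control material:

    indirect CV_I = √(CV_Total² − CV_A²).

When CV_A ≥ CV_Total the estimate is undefined and the package raises an
explicit error rather than returning 0 or NaN.

### Choosing the conversion formula

The Gaussian conversion is accurate for CVs up to about 15% and usable to
about 20%; beyond that the error propagation in ratios of near-Gaussian
variables biases it downward, while the lognormal formula stays accurate
to at least ln-CV 50%.  By default the package applies the lognormal
formula whenever the Gaussian-path CV_Total exceeds 20% (a value exactly
at the threshold keeps the Gaussian path).  The threshold is a package
default inferred from the accuracy behaviour above, not a law; it can be
overridden per analyte (`scale_override` / `--scale`), and every report
records which path was used.  The two formulas agree closely below 20%,
so the choice matters little exactly where it is hardest to make.

## The central-peak estimator

Routine data mix the healthy peak with pathological changes, so a plain
SD (even of Box-Cox transformed ratios) is badly biased.  The estimator
in `peak_fit` is a robust fit with three ingredients:

1. **Mode location.**  For a candidate exponent λ the ratios are
   transformed and the mode of the transformed density is located on a
   smoothed histogram (≈√n bins over the central 99% of the data,
   triangular 5-bin smoothing).
2. **Truncated-ML core fit.**  A normal distribution is fitted by maximum
   likelihood to the data inside a window, treating the window as a
   truncation interval.  Because the truncated normal with fixed support
   is a two-parameter exponential family, the MLE equals moment matching
   of the truncated mean and variance; it is solved by an
   Aitken-accelerated fixed-point iteration on prefix sums of the sorted
   sample, so each window costs O(log n) after one sort.  The window
   starts as the central 80% quantile band around the mode (widened to
   90% when it would hold fewer than 1,000 points) and is then re-centred
   iteratively at μ̂ ± k·σ̂ so that tail contamination swallowed by the
   initial band is shed.
3. **Penalized χ² model selection over λ.**  Each λ on a two-stage grid
   (−2 … 2 in 0.1 steps, then 0.01 steps around the coarse optimum) is
   scored by the reduced χ² between the fitted truncated normal and the
   observed histogram over the core bins (Freedman–Diaconis width, at
   least 50 bins), plus a log penalty when the core holds implausibly few
   points — degenerate transforms that isolate a spike score well on
   normality but fail the penalty.  Ties are broken toward λ = 1, then
   λ = 0.  For samples above 200,000 ratios the grid search runs on a
   seeded subsample; the final fit always uses all data.

### Two window widths, not one

Window width k trades robustness against discrimination.  Wide windows
(k ≈ 1.8 SD) are needed to *rank* candidate exponents — inside a narrow
window every smooth unimodal density looks Gaussian, and λ selection
collapses.  Narrow windows are needed for the *scale* estimate: a
pathological subpopulation shifted by ×1.5 sits only ≈2.9 SD from the
peak of a 10% ln-CV core, and a 1.8-SD window swallows enough of its
inner shoulder to inflate σ̂ by >20% at a 30% pathological fraction.
The estimator therefore selects λ with k = 1.8 (`select_k`) and then
re-fits σ at the chosen λ inside a k = 1.3 window (`sigma_k`).  On a
truly Gaussian core the truncated MLE is consistent under any fixed k, so
the narrow final window costs variance, not bias; under 20–30%
step-shift contamination it keeps the inflation of the recovered CV below
~10% relative where the naive SD is off by 60–90%.

### Known behaviour and limitations

* **Gaussian parents above CV ≈ 15%.**  The ratio of two Gaussians is
  heavier-tailed than any Box-Cox-normal; a core-focused fit then reads
  slightly below the full-sample value (estimates ≈14.7 at input 15,
  ≈19.3 at input 20).  This mirrors the validation-grid behaviour of the
  approach and is intrinsic: the full-sample profile-ML fit of the same
  samples reads *high* (≈15.4 at input 15), so "the" CV of such a ratio
  distribution depends on how much tail one admits.  Real analytes with
  CV_Total near 20% should be interpreted with this spread in mind.
* **Gradual drift.**  A pathological *step* of ×1.5 between two visits is
  well separated from the healthy peak and is shed by the core fit.  A
  gradual *trend* of the same total magnitude spread over a series
  produces per-ratio shifts within ~1.5 SD of the peak; these merge into
  the core and no central-peak estimator can remove them (the synthetic
  `trend` model shows ≈15–20% inflation at a 25% pathological fraction).
* **Very heavy skew.**  Distributions that no Box-Cox exponent in
  [−2, 2] renders near-Gaussian fail model selection; the fit reports its
  χ² score and per-λ trace so such cases are visible.

## Bootstrap confidence intervals

`bootstrap_ci` draws nonparametric case resamples of the ratio sample
(multinomial counts over the sorted values, so replicates need no
re-sorting), refits the full central-peak estimator on each replicate,
pushes each through the same conversion scale as the point estimate and
the CV_A subtraction, and reports percentile 2.5/97.5 intervals for both
σ and the indirect CV_I (default 1,000 repetitions).  Replicates where
CV_A exceeds the replicate's CV_Total are counted; if more than 10% fail
the interval is flagged unreliable.  Everything is reproducible from the
seed.  Resampling ratios (not patients) matches the view of the ratio
sample as the estimation unit; patient-level resampling would widen
intervals slightly when patients contribute many correlated pairs.

## Ratio construction

Per patient, results are sorted by time (ties broken by value, so the
build is deterministic) and each adjacent pair yields one ratio
later/earlier.  Pairs overlap — k results give k−1 ratios — which
maximizes the sample and matches the reading of "consecutive results";
`disjoint_pairs` provides the non-overlapping alternative (⌊k/2⌋ ratios).
The later/earlier orientation follows the reference-change-value
convention; for a symmetric central peak the CV estimate is orientation-
insensitive (the lognormal path is exactly reciprocal-invariant).  No
time-gap limits are applied by default; `min_gap`/`max_gap` let users
exclude same-day duplicates or multi-year gaps.  Data-sufficiency
warnings (fewer than 5,000 ratios, or a suspected pathological fraction
≥30%) are advisory and never block estimation.

## Synthetic data

Two generators drive validation and testing; both are deterministic given
a seed.

`simulate_ratio_sample` draws i.i.d. pairs from one parent — Gaussian
N(μ, μ·CV/100) truncated to >0 by redrawing (truncation mass <3e−7 at
CV 20%, so no renormalization is applied), or lognormal with σ_x chosen
to hit a target ln-CV — and forms their ratios.  A configurable fraction
of ratios gets the numerator multiplied by a pathological shift (×1.5 by
default, or its reciprocal 50/50), emulating sustained change between the
two measurements.  The Gaussian parent mean defaults to 100; ratios are
scale-free so the value only affects truncation.

`simulate_lis_dataset` emulates a routine extract: each patient draws a
homeostatic set point from a between-subject distribution, then serial
results scatter around it with independent multiplicative lognormal
within-subject (CV_I) and analytical (CV_A) components; visits are spaced
by exponential inter-visit times (mean 30 days).  A configurable fraction
of patients is pathological, with either a sustained step shift after a
random change point or a monotone trend across the series (sign
randomized).  The generator does **not** model diurnal rhythms, seasonal
or age/sex trends in set points, preanalytical shifts between collection
sites, or menstrual-cycle effects — passing recovery tests on this
synthetic data therefore demonstrates correctness of the estimation
machinery under the stated model, not immunity to those real-world
effects, which a direct study controls by design.

The validation harness `run_monte_carlo_table` reproduces the
input-vs-estimated CV grid (Gaussian 2.5–20%, lognormal 5–50%).  Full
scale is one million ratios × 100 iterations per cell; the packaged tests
and the acceptance script run the same harness at 100,000 ratios × 10
iterations, which leaves the Monte Carlo error of each cell mean near
0.1 CV points while keeping a desk run in minutes.

## Numerical choices

* Box-Cox at λ = 0 uses the exact logarithm branch, never a small-λ
  approximation; `scipy.special.boxcox` supplies the transform.
* The truncated-ML fixed point iterates to 1e−9 relative tolerance (1e−7
  while the window is still moving), with Aitken steps rejected when they
  jump outside a plausible region — the early window-moving iterations
  are not yet in the linear regime.
* Degenerate inputs fail loudly: fewer than 500 ratios, zero variance in
  the core, or no λ achieving a positive σ all raise `ValueError` with
  the reason named.
* Reports keep full precision; display fields round half-to-even to one
  decimal for CVs and three decimals for Box-Cox(σ).
* All randomness flows from `numpy.random.default_rng` seeds carried in
  the configuration objects; identical inputs and seed give bit-identical
  fits.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `central_span` | 0.8 | initial quantile core around the mode (0.9 if <1,000 points inside) |
| `select_k` | 1.8 | window half-width (SD) for λ scoring |
| `sigma_k` | 1.3 | window half-width (SD) for the final σ fit |
| λ grid | −2 … 2, 0.1 then 0.01 | covers inverse through square transforms |
| `min_bins` | 50 | χ² histogram floor |
| `max_grid_n` | 200,000 | subsample cap for the λ search |
| `min_ratios` | 500 | hard floor (soft recommendation: 5,000) |
| scale threshold | 20% | Gaussian→lognormal switch on CV_Total |
| `n_boot` | 1,000 | bootstrap repetitions |
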