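"""Central Box-Cox-normal peak fitting: oracle checks, robustness, bootstrap."""

import dataclasses

import numpy as np
import pytest

from ratiocv import (
    AnalyticalNoiseError,
    FitConfig,
    SimulationSpec,
    bootstrap_ci,
    estimate_cvi,
    fit_central_peak,
    lncv_from_ratio_sigma,
    profile_ml_boxcox_fit,
    sigma_for_target_lncv,
    simulate_ratio_sample,
)


def _lognormal_ratios(lncv, n, seed, contamination=0.0):
    spec = SimulationSpec(distribution="lognormal", cv_percent=lncv, n_ratios=n,
                          seed=seed, contamination_fraction=contamination)
    return simulate_ratio_sample(spec).ratios


class TestFitCentralPeak:
    def test_hard_floor_on_sample_size(self):
        with pytest.raises(ValueError, match="at least 500"):
            fit_central_peak(np.ones(400) * 1.01)

    def test_degenerate_sample_names_zero_variance(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_central_peak(np.full(1000, 1.23))

    def test_deterministic_given_seed(self):
        z = _lognormal_ratios(15.0, 5000, seed=11)
        cfg = FitConfig(seed=42)
        a = fit_central_peak(z, cfg)
        b = fit_central_peak(z, cfg)
        assert a == b  # bit-identical dataclasses, diagnostics included

    def test_recovers_lognormal_sigma(self):
        z = _lognormal_ratios(20.0, 100_000, seed=3)
        fit = fit_central_peak(z, FitConfig(seed=0))
        true_sigma = np.sqrt(2.0) * sigma_for_target_lncv(20.0)
        assert fit.sigma_t == pytest.approx(true_sigma, rel=0.02)
        assert abs(fit.lam) <= 0.2

    def test_diagnostic_trace_spans_the_grid(self):
        z = _lognormal_ratios(10.0, 5000, seed=1)
        fit = fit_central_peak(z, FitConfig(seed=0))
        lams = [lam for lam, _, _ in fit.diagnostics]
        assert min(lams) == pytest.approx(-2.0)
        assert max(lams) == pytest.approx(2.0)
        assert fit.n_used <= fit.n_ratios


class TestProfileMlOracle:
    def test_lognormal_sample_selects_log_transform(self):
        z = _lognormal_ratios(20.0, 100_000, seed=5)
        fit = profile_ml_boxcox_fit(z)
        assert -0.1 <= fit.lam <= 0.1

    def test_gaussian_peak_around_one_recovers_sigma(self):
        # already normal at z ~ 1: transform is locally the identity there
        rng = np.random.default_rng(8)
        z = rng.normal(1.0, 0.05, 20_000)
        z = z[z > 0]
        fit = profile_ml_boxcox_fit(z)
        assert fit.sigma_t == pytest.approx(0.05, rel=0.02)

    @pytest.mark.parametrize("lncv", [5.0, 20.0])
    def test_central_fit_matches_oracle_on_clean_lognormal(self, lncv):
        for seed in (0, 1):
            z = _lognormal_ratios(lncv, 100_000, seed=seed)
            central = fit_central_peak(z, FitConfig(seed=seed))
            oracle = profile_ml_boxcox_fit(z)
            assert central.sigma_t == pytest.approx(oracle.sigma_t, rel=0.02)


class TestRobustness:
    def test_contaminated_sample_shifts_naive_sd_not_core_fit(self):
        clean = _lognormal_ratios(10.0, 50_000, seed=21)
        dirty = _lognormal_ratios(10.0, 50_000, seed=21, contamination=0.2)
        cv_clean = lncv_from_ratio_sigma(fit_central_peak(clean, FitConfig(seed=0)).sigma_t)
        cv_dirty = lncv_from_ratio_sigma(fit_central_peak(dirty, FitConfig(seed=0)).sigma_t)
        cv_naive = lncv_from_ratio_sigma(float(np.std(np.log(dirty))))
        assert cv_dirty == pytest.approx(cv_clean, rel=0.10)
        assert cv_naive > cv_dirty * 1.2

    def test_reciprocal_invariance_of_lognormal_path(self):
        z = _lognormal_ratios(15.0, 50_000, seed=9)
        cfg = FitConfig(seed=0)
        cv_fwd = lncv_from_ratio_sigma(fit_central_peak(z, cfg).sigma_t)
        cv_rev = lncv_from_ratio_sigma(fit_central_peak(1.0 / z, cfg).sigma_t)
        assert cv_rev == pytest.approx(cv_fwd, rel=0.02)


class TestEstimateCvi:
    def test_zero_cva_returns_cv_total(self):
        z = _lognormal_ratios(10.0, 10_000, seed=2)
        est = estimate_cvi(z, cv_a=0.0, config=FitConfig(seed=0))
        assert est.cv_i == est.cv_total
        assert est.scale_used == "gaussian"

    def test_scale_override_is_recorded(self):
        z = _lognormal_ratios(10.0, 10_000, seed=2)
        est = estimate_cvi(z, cv_a=0.0, config=FitConfig(seed=0),
                           scale_override="lognormal")
        assert est.scale_used == "lognormal"
        assert est.cv_total == pytest.approx(
            lncv_from_ratio_sigma(est.fit.sigma_t))

    def test_automatic_lognormal_scale_for_large_cv(self):
        z = _lognormal_ratios(40.0, 20_000, seed=4)
        est = estimate_cvi(z, cv_a=0.0, config=FitConfig(seed=0))
        assert est.scale_used == "lognormal"

    def test_dominant_analytical_noise_raises(self):
        z = _lognormal_ratios(5.0, 10_000, seed=6)
        with pytest.raises(AnalyticalNoiseError):
            estimate_cvi(z, cv_a=30.0, config=FitConfig(seed=0))


class TestBootstrap:
    def test_single_replicate_gives_degenerate_interval(self):
        z = _lognormal_ratios(10.0, 2000, seed=13)
        est = bootstrap_ci(z, FitConfig(seed=0), n_boot=1, cv_a=2.0, seed=1)
        assert est.ci_sigma[0] == est.ci_sigma[1]
        assert est.ci_cv_i[0] == est.ci_cv_i[1]
        assert est.n_boot == 1

    def test_reproducible_from_seed(self):
        z = _lognormal_ratios(10.0, 2000, seed=13)
        a = bootstrap_ci(z, FitConfig(seed=0), n_boot=25, cv_a=2.0, seed=7)
        b = bootstrap_ci(z, FitConfig(seed=0), n_boot=25, cv_a=2.0, seed=7)
        assert a == b

    @pytest.mark.parametrize("seed", range(20))
    def test_point_estimate_inside_its_own_interval(self, seed):
        z = _lognormal_ratios(12.0, 2000, seed=100 + seed)
        est = bootstrap_ci(z, FitConfig(seed=0), n_boot=200, cv_a=3.0, seed=seed)
        assert est.ci_cv_i[0] <= est.cv_i <= est.ci_cv_i[1]
        assert est.ci_sigma[0] <= est.fit.sigma_t <= est.ci_sigma[1]

    def test_interval_width_shrinks_like_root_n(self):
        widths = []
        for n in (2500, 10_000, 40_000):
            z = _lognormal_ratios(10.0, n, seed=31)
            est = bootstrap_ci(z, FitConfig(seed=0), n_boot=200, cv_a=0.0, seed=5)
            widths.append(est.ci_cv_i[1] - est.ci_cv_i[0])
        assert widths[0] > widths[1] > widths[2]
        for w_small, w_big in zip(widths, widths[1:]):
            assert 1.4 <= w_small / w_big <= 3.1  # ~2 per 4x n

    def test_invalid_n_boot_rejected(self):
        z = _lognormal_ratios(10.0, 2000, seed=13)
        with pytest.raises(ValueError):
            bootstrap_ci(z, FitConfig(seed=0), n_boot=0, cv_a=0.0, seed=1)
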