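"""The synthetic study generator: distributions, truth, reproducibility."""

import numpy as np
import pytest
from scipy import stats

import fosmod as fm
from fosmod.synthetic_data import EffectSpec, default_effect_spec

from conftest import fit_study, null_effects


class TestSimulateCovariates:
    def test_sample_means_match_configured_population(self):
        """At n=55 the sample means fall within 3 standard errors of the
        configured means (NDI 10.11, age 34.67, neck length 14.98)."""
        cfg = fm.GeneratorConfig(seed=11)
        cov = fm.simulate_covariates(cfg)
        for name in ("ndi", "age", "neck_length"):
            se = cfg.covariate_sds[name] / np.sqrt(55)
            assert abs(cov.column(name).mean() - cfg.covariate_means[name]) < 3 * se
        assert 0.05 < cov.sex.mean() < 0.75  # Bernoulli(0.364) at n=55

    def test_zero_sd_collapses_to_the_mean(self):
        cfg = fm.GeneratorConfig(
            seed=1,
            covariate_sds={"ndi": 0.0, "age": 0.0, "neck_length": 0.0},
        )
        cov = fm.simulate_covariates(cfg)
        assert np.all(cov.ndi == round(cfg.covariate_means["ndi"]))
        assert np.all(cov.age == cfg.covariate_means["age"])
        assert np.all(cov.neck_length == cfg.covariate_means["neck_length"])

    def test_same_seed_is_bit_identical(self):
        a = fm.simulate_covariates(fm.GeneratorConfig(seed=5))
        b = fm.simulate_covariates(fm.GeneratorConfig(seed=5))
        for col in ("ndi", "age", "neck_length", "sex"):
            assert np.array_equal(a.column(col), b.column(col))

    def test_ndi_respects_its_scale(self):
        cov = fm.simulate_covariates(fm.GeneratorConfig(n=500, seed=2))
        assert cov.ndi.min() >= 0 and cov.ndi.max() <= 50
        assert np.array_equal(cov.ndi, np.round(cov.ndi))

    def test_sex_neck_length_correlation_hook(self):
        cfg = fm.GeneratorConfig(n=400, seed=3, neck_length_sex_shift=1.7)
        cov = fm.simulate_covariates(cfg)
        male = cov.sex == 1
        assert cov.neck_length[male].mean() > cov.neck_length[~male].mean() + 1.0


class TestSimulateVarianceField:
    def test_large_prior_df_concentrates_at_the_scale(self):
        cfg = fm.GeneratorConfig(seed=1, d0_true=1e6, s02_true=2.0)
        sigma2 = fm.simulate_variance_field(cfg)
        assert np.all(np.abs(sigma2 - 2.0) < 0.02 * 2.0)

    def test_mean_precision_matches_the_prior(self):
        # E[1/sigma^2] = 1/s02 under the scaled inverse chi-square prior
        cfg = fm.GeneratorConfig(K=100_000, seed=2, d0_true=4.0, s02_true=2.0)
        sigma2 = fm.simulate_variance_field(cfg)
        assert abs(np.mean(1.0 / sigma2) - 0.5) < 0.01 * 0.5

    def test_fixed_profile_overrides_draws(self):
        profile = lambda t: 1.0 + t
        cfg = fm.GeneratorConfig(K=11, seed=3, variance_profile=profile)
        sigma2 = fm.simulate_variance_field(cfg)
        assert np.allclose(sigma2, 1.0 + fm.TimeGrid.uniform(11).points)

    def test_same_seed_identical_field(self):
        a = fm.simulate_variance_field(fm.GeneratorConfig(seed=9))
        b = fm.simulate_variance_field(fm.GeneratorConfig(seed=9))
        assert np.array_equal(a, b)


class TestCoefficientFunctions:
    def test_all_null_spec_leaves_only_the_template(self):
        cfg = fm.GeneratorConfig(seed=0, effect_spec=null_effects())
        grid = fm.TimeGrid.uniform(50)
        names, beta = fm.make_coefficient_functions(cfg, grid)
        assert names[0] == "intercept"
        assert np.allclose(beta[0], cfg.amplitude_base * -np.cos(2 * np.pi * grid.points))
        assert np.all(beta[1:] == 0.0)

    def test_bump_peaks_at_center_and_vanishes_outside(self):
        spec = EffectSpec("bump", amplitude=2.0, center=0.5, width=0.2)
        t = np.array([0.3, 0.5, 0.39, 0.61])
        vals = spec.evaluate(t)
        assert vals[1] == 2.0
        assert vals[0] == 0.0 and vals[3] == 0.0

    def test_bump_window_must_stay_inside_unit_interval(self):
        with pytest.raises(ValueError):
            EffectSpec("bump", amplitude=1.0, center=0.05, width=0.3)

    def test_template_velocity_amplitude_scales_as_amplitude_over_duration(self):
        grid = fm.TimeGrid.uniform(200)
        ratios = []
        for a, T in ((40.0, 2.0), (60.0, 3.0), (80.0, 6.0)):
            cfg = fm.GeneratorConfig(seed=0, response="velocity", amplitude_base=a, duration_base=T)
            _, beta = fm.make_coefficient_functions(cfg, grid)
            ratios.append(np.max(np.abs(beta[0])) / (a / T))
        assert np.allclose(ratios, 2 * np.pi, rtol=1e-4)


class TestSimulateStudy:
    def test_zero_noise_fit_recovers_truth(self):
        cfg = fm.GeneratorConfig(seed=6, variance_profile=np.zeros(100))
        study = fm.simulate_study(cfg)
        fit, _ = fit_study(study)
        assert np.max(np.abs(fit.beta_hat - study.truth_beta)) < 1e-8

    def test_mean_curve_range_matches_the_template_scale(self, default_study):
        """The mean simulated angle curve has range ~ 2 * amplitude_base,
        i.e. a range of motion on the scale observed in the study sample."""
        mean_curve = default_study.curves.values.mean(axis=0)
        rom = mean_curve.max() - mean_curve.min()
        assert abs(rom - 2 * default_study.config.amplitude_base) < 0.05 * rom

    def test_pointwise_confidence_intervals_cover_the_truth(self):
        """95% CIs for beta_ndi(t) cover the truth at ~95% of (replicate,
        time) pairs over 50 replicates - the model is correctly specified."""
        hits = total = 0
        for rep in range(50):
            study = fm.simulate_study(fm.GeneratorConfig(seed=1300 + rep))
            fit, _ = fit_study(study)
            j = fit.coefficient_index("ndi")
            crit = stats.t.ppf(0.975, fit.design.residual_df)
            lo = fit.beta_hat[j] - crit * fit.se_ordinary[j]
            hi = fit.beta_hat[j] + crit * fit.se_ordinary[j]
            truth = study.truth_beta[j]
            hits += np.sum((truth >= lo) & (truth <= hi))
            total += truth.size
        assert 0.93 <= hits / total <= 0.97

    def test_n_not_larger_than_p_is_an_error(self):
        with pytest.raises(ValueError):
            fm.simulate_study(fm.GeneratorConfig(n=5, seed=0))

    def test_bit_reproducibility(self):
        a = fm.simulate_study(fm.GeneratorConfig(seed=21))
        b = fm.simulate_study(fm.GeneratorConfig(seed=21))
        assert np.array_equal(a.curves.values, b.curves.values)
        assert np.array_equal(a.sigma2, b.sigma2)

    def test_smooth_noise_shares_data_across_grids(self):
        cfg = fm.GeneratorConfig(seed=8, noise="smooth")
        s100, s1000 = fm.simulate_study_on_grids(cfg, [100, 1000])
        # identical covariates and identical curves at the shared endpoints
        assert np.array_equal(s100.covariates.ndi, s1000.covariates.ndi)
        assert np.allclose(s100.curves.values[:, 0], s1000.curves.values[:, 0])
        assert np.allclose(s100.curves.values[:, -1], s1000.curves.values[:, -1])

    def test_iid_noise_refuses_multiple_grids(self):
        with pytest.raises(ValueError, match="smooth"):
            fm.simulate_study_on_grids(fm.GeneratorConfig(seed=8), [100, 1000])

    def test_derived_velocity_matches_template_derivative(self):
        cfg = fm.GeneratorConfig(seed=12, variance_profile=np.zeros(100), effect_spec=null_effects())
        study = fm.simulate_study(cfg, include_derivatives=True)
        vel = study.derived["velocity"]
        grid = study.grid.points
        expected = (2 * np.pi * cfg.amplitude_base / cfg.duration_base) * np.sin(2 * np.pi * grid)
        # natural end conditions leave a localized O(h^2) error at the two
        # boundary points; the interior matches the closed form tightly
        err = np.abs(vel.values[0] - expected)
        assert err[5:-5].max() < 1e-3 * np.max(np.abs(expected))
        assert err.max() < 0.05 * np.max(np.abs(expected))

    def test_default_effect_spec_windows_thirty_percent_of_grid(self, default_study):
        j = default_study.coefficient_names.index("ndi")
        support = default_study.truth_beta[j] != 0
        assert 0.25 <= support.mean() <= 0.35
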