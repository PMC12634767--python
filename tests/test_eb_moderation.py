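"""Variance moderation: trigamma inverse, hyperparameters, squeezing, inference."""

import math
import subprocess
import sys

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.special import digamma, polygamma

import fosmod as fm
from fosmod.synthetic_data import EffectSpec

from conftest import fit_study, null_effects


class TestTrigammaInverse:
    def test_known_special_value(self):
        # psi'(1) = pi^2 / 6
        assert np.isclose(fm.trigamma_inverse(np.pi**2 / 6), 1.0, rtol=1e-8)

    @pytest.mark.parametrize("x", [0.01, 0.3, 1.0, 5.0, 40.0, 2000.0])
    def test_forward_evaluate_then_invert(self, x):
        y = float(polygamma(1, x))
        assert np.isclose(fm.trigamma_inverse(y), x, rtol=1e-6)

    @given(st.floats(1e-4, 1e4), st.floats(1e-4, 1e4))
    def test_strictly_decreasing(self, y1, y2):
        if y1 == y2:
            return
        lo, hi = sorted((y1, y2))
        assert fm.trigamma_inverse(lo) > fm.trigamma_inverse(hi)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            fm.trigamma_inverse(0.0)
        with pytest.raises(ValueError):
            fm.trigamma_inverse(-1.0)


class TestEstimateHyperparameters:
    def test_constant_variances_give_infinite_prior_df(self):
        d = 20
        s2 = np.full(50, 3.0)
        params = fm.estimate_hyperparameters(s2, d)
        assert math.isinf(params.d0)
        expected = 3.0 * math.exp(-digamma(d / 2) + math.log(d / 2))
        assert np.isclose(params.s02, expected, rtol=1e-12)

    def test_monte_carlo_recovery_from_the_prior(self, rng):
        d0, s02, d = 4.0, 2.0, 50
        sigma2 = d0 * s02 / stats.chi2.rvs(d0, size=10_000, random_state=rng)
        s2 = sigma2 * stats.chi2.rvs(d, size=10_000, random_state=rng) / d
        params = fm.estimate_hyperparameters(s2, d)
        assert abs(params.d0 - d0) / d0 < 0.15
        assert abs(params.s02 - s02) / s02 < 0.15

    def test_log_variance_moment_formula_matches_simulation(self, rng):
        """E[log s^2] used by the moment estimator agrees with a 1e6-draw
        simulation at (d0, s02, d) = (6, 1, 20) to 3 significant digits."""
        d0, s02, d = 6.0, 1.0, 20
        sigma2 = d0 * s02 / stats.chi2.rvs(d0, size=1_000_000, random_state=rng)
        s2 = sigma2 * stats.chi2.rvs(d, size=1_000_000, random_state=rng) / d
        sim_mean = np.log(s2).mean()
        closed_form = (
            math.log(s02)
            + math.log(d0 / 2)
            - digamma(d0 / 2)
            + digamma(d / 2)
            - math.log(d / 2)
        )
        assert np.isclose(sim_mean, closed_form, atol=5e-3)

    def test_too_few_variances_is_an_error(self):
        with pytest.raises(ValueError):
            fm.estimate_hyperparameters(np.array([1.0]), 10)
        with pytest.raises(ValueError):
            fm.estimate_hyperparameters(np.zeros(10), 10)

    def test_non_positive_variances_excluded_with_warning(self):
        rng = np.random.default_rng(0)
        s2 = np.concatenate([rng.chisquare(10, 200) / 10, [0.0]])
        with pytest.warns(UserWarning, match="non-positive"):
            params = fm.estimate_hyperparameters(s2, 10)
        assert params.s02 > 0

    def test_matches_bioconductor_limma(self, tmp_path):
        """Independent oracle: limma::squeezeVar on the same variances."""
        rng = np.random.default_rng(7)
        sigma2 = 4 * 2 / stats.chi2.rvs(4, size=50, random_state=rng)
        s2 = sigma2 * stats.chi2.rvs(12, size=50, random_state=rng) / 12
        params = fm.estimate_hyperparameters(s2, 12)
        squeezed = fm.squeeze_variances(s2, 12, params)
        s2_file = tmp_path / "s2.txt"
        np.savetxt(s2_file, s2)
        out_file = tmp_path / "out.txt"
        script = (
            f'suppressMessages(library(limma)); s2 <- scan("{s2_file}", quiet=TRUE); '
            f"out <- squeezeVar(s2, df=12); "
            f'write(c(out$df.prior, out$var.prior, out$var.post), "{out_file}", ncolumns=1)'
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = np.loadtxt(out_file)
        assert np.isclose(params.d0, ref[0], rtol=1e-5)
        assert np.isclose(params.s02, ref[1], rtol=1e-5)
        assert np.allclose(squeezed, ref[2:], rtol=1e-5)


class TestSqueezeVariances:
    def test_formula_limits(self, rng):
        s2 = rng.chisquare(5, 30)
        assert np.array_equal(fm.squeeze_variances(s2, 10, fm.ModerationParams(0.0, 1.7)), s2)
        half = fm.squeeze_variances(s2, 10, fm.ModerationParams(10.0, 1.7))
        assert np.allclose(half, (1.7 + s2) / 2, rtol=1e-12)
        inf = fm.squeeze_variances(s2, 10, fm.ModerationParams(math.inf, 1.7))
        assert np.all(inf == 1.7)

    @given(st.floats(0.1, 100), st.floats(0.1, 100), st.integers(1, 100))
    def test_strict_convex_combination(self, d0, s02, d):
        rng = np.random.default_rng(1)
        s2 = rng.chisquare(5, 20)
        squeezed = fm.squeeze_variances(s2, d, fm.ModerationParams(d0, s02))
        lo, hi = np.minimum(s2, s02), np.maximum(s2, s02)
        assert np.all(squeezed >= lo - 1e-12) and np.all(squeezed <= hi + 1e-12)
        # weight d/(d0+d) on s2
        assert np.allclose(squeezed, (d0 * s02 + d * s2) / (d0 + d), rtol=1e-12)


class TestModeratedInference:
    def test_d0_zero_reduces_to_ordinary_t(self, default_fit):
        fit, _ = default_fit
        mod = fm.moderated_inference(fit, fm.ModerationParams(0.0, 1.0))
        assert np.max(np.abs(mod.t_mod - fit.t_ordinary)) < 1e-12
        assert np.max(np.abs(mod.p_mod - fit.p_ordinary)) < 1e-12

    def test_t_cdf_oracle_with_prior_df(self):
        # beta=1, s2_tilde=0.25, v_jj=1, d=10, d0=5  =>  t=2, p=2(1-F_t15(2))
        t = 1.0 / (np.sqrt(0.25) * 1.0)
        assert np.isclose(t, 2.0)
        p = 2 * stats.t.sf(t, 15)
        assert np.isclose(p, 2 * (1 - stats.t.cdf(2.0, 15)), rtol=1e-14)

    def test_infinite_prior_df_uses_standard_normal(self, default_fit):
        fit, _ = default_fit
        mod = fm.moderated_inference(fit, fm.ModerationParams(math.inf, 2.0))
        assert np.all(mod.s2_tilde == 2.0)
        j = fit.coefficient_index("ndi")
        expected = 2 * stats.norm.sf(np.abs(mod.t_mod[j]))
        assert np.allclose(mod.p_mod[j], expected, rtol=1e-12)

    def test_moderation_never_touches_coefficients(self, default_study):
        fit, mod = fit_study(default_study)
        before = fit.beta_hat.copy()
        assert mod.t_mod.shape == fit.beta_hat.shape
        assert np.array_equal(fit.beta_hat, before)  # bitwise

    def test_zero_coefficient_gives_p_one(self, default_fit):
        fit, mod = default_fit
        t = np.where(fit.beta_hat == 0, mod.t_mod, 0.0)
        assert np.all(np.abs(t) == 0)

    def test_hyperparameter_recovery_through_the_pipeline(self):
        """Fitted residual variances at K=2000, d=50 recover the generating
        prior (d0, s02) = (4, 1) with median relative error < 10%."""
        errors = []
        for rep in range(20):
            cfg = fm.GeneratorConfig(
                seed=800 + rep, K=2000, s02_true=1.0, effect_spec=null_effects()
            )
            study = fm.simulate_study(cfg)
            fit = fm.fit_pointwise(study.curves, fm.build_design(study.covariates))
            params = fm.estimate_hyperparameters(fit.s2, fit.design.residual_df)
            errors.append((abs(params.d0 - 4) / 4, abs(params.s02 - 1) / 1))
        errors = np.asarray(errors)
        assert np.median(errors[:, 0]) < 0.10
        assert np.median(errors[:, 1]) < 0.10

    def test_moderated_null_pvalues_are_uniform(self):
        pooled = []
        for rep in range(5):
            cfg = fm.GeneratorConfig(seed=900 + rep, K=400, effect_spec=null_effects())
            study = fm.simulate_study(cfg)
            fit, mod = fit_study(study)
            pooled.append(mod.p_mod[fit.coefficient_index("neck_length")])
        ks = stats.kstest(np.concatenate(pooled), "uniform")
        assert ks.pvalue > 0.01

    def test_moderation_gains_power_on_affected_times(self):
        """With heterogeneous variances from the prior, the moderated p on
        truly affected times is on average no larger than the ordinary p."""
        es = null_effects()
        es["ndi"] = EffectSpec("bump", amplitude=0.8, center=0.25, width=0.3)
        mean_ord, mean_mod = [], []
        for rep in range(20):
            study = fm.simulate_study(fm.GeneratorConfig(seed=1000 + rep, effect_spec=es))
            fit, mod = fit_study(study)
            j = fit.coefficient_index("ndi")
            affected = study.truth_beta[j] != 0
            mean_ord.append(fit.p_ordinary[j][affected].mean())
            mean_mod.append(mod.p_mod[j][affected].mean())
        assert np.mean(mean_mod) <= np.mean(mean_ord)
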