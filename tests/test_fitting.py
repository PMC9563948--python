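import numpy as np
import pytest
from scipy.stats import chi2

from lungdr.exceptions import LungDRError
from lungdr.fitting import (
    OSModel,
    OSResults,
    correlation_matrix,
    correlation_strength,
    cross_validate,
    lr_test,
    model_scores,
    neg2_log_likelihood,
    overdispersion_factor,
    profile_ci,
)
from lungdr.models import RadioParams, get_model
from lungdr.reference import model2_reference_params
from lungdr.synthetic import SyntheticDesign, generate_dataset

from conftest import make_cohort

STAGES = ("I", "II", "IIIA", "IIIB")


def flat_probit_params(eqd50=60.0):
    """Model-1 parameters whose prediction at 60 Gy/2 Gy/no repop is 0.5."""
    return RadioParams(alpha_beta=10.0, lam=0.0, t_k=20.0, m=0.3,
                       eqd2_tum50={s: eqd50 for s in STAGES})


def results_at(cohorts, spec, params) -> OSResults:
    """An OSResults evaluated at given parameters (no optimisation)."""
    model = OSModel(cohorts, spec)
    values = model.layout.values_from_params(params)
    return OSResults(model=model, values=values,
                     z_opt=model.layout.pack(values),
                     neg2_loglik=model.neg2_loglik_values(values),
                     converged=True, n_starts_used=0)


class TestLikelihood:
    def test_half_probability_single_cohort(self):
        # N = 10, x = 5, p = 0.5  ->  -2 * 10 * ln 0.5
        c = make_cohort(n_patients=10, os2_observed=50.0, treatment="RT",
                        duration_days=40.0)
        val = neg2_log_likelihood(flat_probit_params(), [c], get_model("model1"))
        assert val == pytest.approx(13.8629, abs=1e-3)

    def test_saturated_fit_is_the_minimum(self):
        c = make_cohort(n_patients=10, os2_observed=50.0, treatment="RT")
        spec = get_model("model1")
        at_half = neg2_log_likelihood(flat_probit_params(), [c], spec)
        for eqd50 in (40.0, 55.0, 70.0, 90.0):  # predictions != 0.5
            other = neg2_log_likelihood(flat_probit_params(eqd50), [c], spec)
            assert other >= at_half - 1e-9

    def test_zero_survivors_stay_finite(self):
        c = make_cohort(n_patients=50, os2_observed=0.0, treatment="RT")
        val = neg2_log_likelihood(flat_probit_params(eqd50=20.0), [c],
                                  get_model("model1"))
        assert np.isfinite(val)

    def test_scalar_and_vector_paths_agree(self, default_dataset):
        from lungdr.radiobiology import predict_cohort_os
        from lungdr.reference import model5_reference_params

        spec = get_model("model5")
        p = model5_reference_params()
        model = OSModel(default_dataset, spec)
        vec = 100 * model.predict_from_values(model.layout.values_from_params(p))
        scal = [predict_cohort_os(c, p, spec) for c in default_dataset]
        assert np.allclose(vec, scal, rtol=1e-10)


class TestScoresAndTests:
    def test_aic_from_printed_loglik(self):
        class Stub:
            neg2_loglik, n_params = 6468.6, 8
            aic = neg2_loglik + 2 * n_params

            def qaic(self, phi):
                return self.neg2_loglik / phi + 2 * self.n_params

        assert model_scores(Stub())["aic"] == pytest.approx(6484.6)
        Stub.neg2_loglik, Stub.n_params = 6329.4, 21
        Stub.aic = 6329.4 + 42
        scores = model_scores(Stub(), phi=1.0)
        assert scores["aic"] == pytest.approx(6371.4)
        assert scores["qaic"] == scores["aic"]

    def test_qaic_discounts_goodness_of_fit(self):
        class Stub:
            neg2_loglik, n_params, aic = 1000.0, 10, 1020.0

            def qaic(self, phi):
                return self.neg2_loglik / phi + 2 * self.n_params

        assert model_scores(Stub(), phi=2.0)["qaic"] == pytest.approx(520.0)
        with pytest.raises(LungDRError):
            model_scores(Stub(), phi=0.0)

    def test_lr_test_values(self, default_dataset):
        spec1, spec2 = get_model("model1"), get_model("model2")
        a = results_at(default_dataset, spec1, flat_probit_params())
        b = results_at(default_dataset, spec2, model2_reference_params())
        # impose -2logL values with known chi-square tails (df = 13 - 8 = 5)
        a.neg2_loglik, b.neg2_loglik = 103.84, 100.0
        assert lr_test(a, b) == pytest.approx(float(chi2.sf(3.84, 5)))
        b.neg2_loglik = 103.84
        assert lr_test(a, b) == 1.0
        # the printed probit vs chemo-era model difference: 103.8 on 5 df
        a.neg2_loglik, b.neg2_loglik = 6468.6, 6364.8
        p = lr_test(a, b)
        assert 0 < p < 1e-19

    def test_non_nested_pairs_rejected(self, default_dataset):
        a = results_at(default_dataset, get_model("model1"),
                       flat_probit_params())
        with pytest.raises(LungDRError):
            lr_test(a, a)


class TestFitting:
    def test_same_seed_same_fit(self, default_dataset):
        m = OSModel(default_dataset, "model1")
        r1 = m.fit(n_starts=3, seed=5)
        r2 = OSModel(default_dataset, "model1").fit(n_starts=3, seed=5)
        assert r1.neg2_loglik == r2.neg2_loglik
        assert np.array_equal(r1.values, r2.values)

    def test_estimate_beats_truth(self, model2_dataset_x10):
        m = OSModel(model2_dataset_x10, "model2")
        res = m.fit(n_starts=4, seed=2)
        assert res.converged
        assert res.neg2_loglik <= m.neg2_loglik(model2_reference_params()) + 1e-6
        assert res.aic == res.neg2_loglik + 2 * res.n_params

    def test_nesting_never_hurts_loglik(self, model2_dataset_x10):
        r1 = OSModel(model2_dataset_x10, "model1").fit(n_starts=3, seed=1)
        r2 = OSModel(model2_dataset_x10, "model2").fit(n_starts=4, seed=1)
        assert r2.neg2_loglik <= r1.neg2_loglik + 1e-6
        assert lr_test(r1, r2) < 1e-6  # underflows to 0 for huge differences

    def test_summary_mentions_model_and_fit(self, default_dataset):
        res = OSModel(default_dataset, "model1").fit(n_starts=2, seed=0)
        text = res.summary()
        assert "model1" in text and "AIC" in text
        assert f"{res.neg2_loglik:.1f}" in text


class TestProfileCI:
    def test_quadratic_surface_hits_3p84_rule(self, analytic_fit_factory):
        # -2logL = 7 + ((a - 2)/0.5)^2 + ((b - 1)/1.3)^2
        fit = analytic_fit_factory(
            lambda v: 7 + ((v[0] - 2) / 0.5) ** 2 + ((v[1] - 1) / 1.3) ** 2,
            optimum=[2.0, 1.0], names=["a", "b"])
        ci = profile_ci(fit, "a")
        half = 0.5 * np.sqrt(chi2.ppf(0.95, 1))
        assert ci.lower == pytest.approx(2 - half, abs=0.005)
        assert ci.upper == pytest.approx(2 + half, abs=0.005)
        assert not ci.truncated_low and not ci.truncated_high
        assert ci.lower <= 2.0 <= ci.upper

    def test_box_edge_truncates(self, analytic_fit_factory):
        fit = analytic_fit_factory(
            lambda v: ((v[0] - 2) / 0.5) ** 2 + v[1] ** 2,
            optimum=[2.0, 0.0], names=["a", "b"],
            lower=[0.0, -5.0], upper=[2.5, 5.0])
        ci = profile_ci(fit, "a")
        assert ci.truncated_high and ci.upper == pytest.approx(2.5)
        assert not ci.truncated_low

    def test_overdispersion_widens_interval(self, analytic_fit_factory):
        fun = lambda v: ((v[0] - 2) / 0.5) ** 2 + v[1] ** 2
        fit = analytic_fit_factory(fun, [2.0, 0.0], names=["a", "b"])
        plain = profile_ci(fit, "a")
        wide = profile_ci(fit, "a", phi=1.5)
        assert wide.upper - wide.lower > plain.upper - plain.lower

    def test_real_model_interval_contains_mle(self, model2_dataset_x10):
        res = OSModel(model2_dataset_x10, "model1").fit(n_starts=3, seed=1)
        ci = res.profile_ci("lam_all")
        est = res.value_of("lam_all")
        if not (ci.truncated_low or ci.truncated_high):
            assert ci.lower <= est <= ci.upper
        assert ci.upper > ci.lower


class TestCorrelationMatrix:
    def test_bivariate_gaussian_recovered(self, analytic_fit_factory):
        rho = 0.6
        P = np.linalg.inv(np.array([[1.0, rho], [rho, 1.0]]))

        fit = analytic_fit_factory(lambda v: float(v @ P @ v),
                                   optimum=[0.0, 0.0], names=["a", "b"],
                                   lower=[-5, -5], upper=[5, 5])
        corr = correlation_matrix(fit)
        assert corr.loc["a", "b"] == pytest.approx(rho, abs=1e-3)
        assert corr.loc["a", "a"] == 1.0

    def test_separable_likelihood_uncorrelated(self, analytic_fit_factory):
        fit = analytic_fit_factory(lambda v: v[0] ** 2 + 3 * v[1] ** 2,
                                   optimum=[0.0, 0.0], names=["a", "b"],
                                   lower=[-5, -5], upper=[5, 5])
        corr = correlation_matrix(fit)
        assert abs(corr.loc["a", "b"]) < 1e-6

    def test_real_fit_matrix_is_well_formed(self, model2_dataset_x10):
        """Either a well-formed matrix or a singular-Hessian error naming
        the unidentified direction (stage I/II parameters can be nearly
        flat when those stages carry almost no patients)."""
        import warnings

        from lungdr.exceptions import SingularHessianError

        res = OSModel(model2_dataset_x10, "model1").fit(n_starts=3, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                corr = res.correlation_matrix()
            except SingularHessianError as exc:
                assert exc.null_directions
                return
        assert np.allclose(np.diag(corr.values), 1.0)
        assert (corr.values <= 1 + 1e-12).all() and (corr.values >= -1 - 1e-12).all()
        assert np.allclose(corr.values, corr.values.T)

    def test_strength_labels(self):
        assert correlation_strength(0.75) == "strong"
        assert correlation_strength(-0.5) == "moderate"
        assert correlation_strength(0.1) == "weak"


class TestOverdispersion:
    def test_binomial_data_give_phi_near_one(self, model2_dataset_x10):
        # Pearson statistic over residual df calibrates at the refitted MLE
        res = OSModel(model2_dataset_x10, "model2").fit(n_starts=4, seed=2)
        od = overdispersion_factor(res)
        assert 0.4 < od.phi < 1.8
        assert od.rms_ratio == pytest.approx(np.sqrt(od.phi))

    def test_beta_binomial_data_inflate_phi(self):
        base = SyntheticDesign(seed=21, truth=model2_reference_params(),
                               truth_spec="model2", patients_multiplier=10.0)
        noisy = SyntheticDesign(seed=21, truth=model2_reference_params(),
                                truth_spec="model2", patients_multiplier=10.0,
                                overdispersion_rho=0.02)
        spec = get_model("model2")
        p = model2_reference_params()
        phi_base = overdispersion_factor(
            results_at(generate_dataset(base), spec, p)).phi
        phi_noisy = overdispersion_factor(
            results_at(generate_dataset(noisy), spec, p)).phi
        assert phi_noisy > phi_base
        assert phi_noisy > 2.0

    def test_needs_residual_dof(self, default_dataset):
        res = results_at(default_dataset[:8], get_model("model1"),
                         flat_probit_params())
        with pytest.raises(LungDRError):
            overdispersion_factor(res)


class TestCrossValidation:
    def test_deterministic_and_partitioned(self, default_dataset):
        r1 = cross_validate(default_dataset, "model1", k_folds=5, seed=9,
                            n_starts=2)
        r2 = cross_validate(default_dataset, "model1", k_folds=5, seed=9,
                            n_starts=2)
        assert r1.score == r2.score
        assert len(r1.fold_scores) + r1.n_folds_skipped == 5

    def test_true_model_beats_misspecified(self, model2_dataset_x10):
        """On data generated from the chemo-era model, the generating spec
        cross-validates better than the probit-only one."""
        good = cross_validate(model2_dataset_x10, "model2", k_folds=5,
                              seed=4, n_starts=3)
        bad = cross_validate(model2_dataset_x10, "model1", k_folds=5,
                             seed=4, n_starts=3)
        assert good.score <= bad.score
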