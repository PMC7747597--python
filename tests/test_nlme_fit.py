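"""FOCE-I objective, empirical Bayes estimates, shrinkage, and diagnostics."""

import numpy as np
import pytest

import doripk as dk
from doripk.nlme_fit import (
    FoceiProblem,
    _published_refs,
    marginal_ofv_agq,
    published_params,
)
from doripk.pop_model import PUBLISHED_FINAL_MODEL as MODEL
from doripk.pop_model import OmegaMatrix, ResidualSpec

ZERO_OMEGA = OmegaMatrix(0.0, 0.0, 0.0, 0.0, 0.0)


def _subset(ds, idx):
    return dk.StudyDataset(subjects=tuple(ds.subjects[i] for i in idx), loq=ds.loq)


class TestOfvFocei:
    def test_zero_omega_reduces_to_fixed_effect_gaussian(self, study_cohort):
        """With no random effects the OFV is the plain Gaussian -2 log likelihood."""
        sigma = MODEL.resid.sigma
        ofv = dk.ofv_focei(MODEL.theta, ZERO_OMEGA, MODEL.resid, study_cohort)
        expected = 0.0
        for s in dk.apply_loq_policy(study_cohort, "exclude").subjects:
            ip = dk.individual_params(MODEL.theta, ZERO_OMEGA, s.covariates, np.zeros(5))
            times = [o.time for o in s.observations if o.time > 0]
            pred = dk.concentration_profile(ip, s.doses, times)
            for o, f in zip([o for o in s.observations if o.time > 0], pred):
                r = np.log(o.concentration) - np.log(f)
                expected += r**2 / sigma**2 + np.log(2 * np.pi * sigma**2)
        assert ofv == pytest.approx(expected, abs=1e-6)

    def test_subject_additivity(self, study_cohort):
        """Subjects contribute independently: OFVs add exactly."""
        a = _subset(study_cohort, range(5))
        b = _subset(study_cohort, [5])
        both = _subset(study_cohort, range(6))
        f = lambda ds: dk.ofv_focei(MODEL.theta, MODEL.omega, MODEL.resid, ds)
        assert f(both) == pytest.approx(f(a) + f(b), abs=1e-6)

    @pytest.mark.parametrize("idx", [(0, 1, 12), (2, 13, 14)])
    def test_matches_quadrature_oracle(self, study_cohort, idx):
        """FOCE-I approximation within 1.0 of the adaptive Gauss-Hermite marginal."""
        small = _subset(study_cohort, idx)
        omega = OmegaMatrix(0.073, 0.222, 0.132, 0.0, 0.0)  # <=2 active dims/subject
        focei = dk.ofv_focei(MODEL.theta, omega, MODEL.resid, small)
        agq = marginal_ofv_agq(MODEL.theta, omega, MODEL.resid, small, n_nodes=31)
        assert abs(focei - agq) <= 1.0


class TestFitPopulation:
    def test_refit_from_optimum_is_stationary(self, study_cohort, base_fit):
        refit = dk.fit_population(study_cohort, dk.BASE_MODEL_SPEC, init=base_fit.params)
        assert abs(refit.ofv - base_fit.ofv) < 0.01

    def test_aic_identity(self, base_fit):
        assert base_fit.aic == pytest.approx(base_fit.ofv + 2 * base_fit.n_params)


class TestEmpiricalBayes:
    def test_no_observations_gives_prior_mode(self):
        cov = dk.CovariateSet(
            ccr=60.0, body_weight=60.0, albumin=2.8, age=60.0, sex="male"
        )
        subj = dk.Subject("x", cov, (dk.DoseEvent("x", 0.0, 500.0, 1.0),), ())
        eta = dk.empirical_bayes(MODEL.theta, MODEL.omega, MODEL.resid, subj)
        np.testing.assert_array_equal(eta, 0.0)

    def test_zero_omega_pins_etas_at_zero(self, study_cohort):
        eta = dk.empirical_bayes(MODEL.theta, ZERO_OMEGA, MODEL.resid, study_cohort.subjects[0])
        np.testing.assert_array_equal(eta, 0.0)

    def test_vanishing_noise_recovers_true_etas(self, rng):
        cov = dk.CovariateSet(
            ccr=70.0, body_weight=60.0, albumin=2.8, age=60.0, sex="male"
        )
        true_eta = np.array([0.12, 0.0, -0.15, 0.2, -0.1])
        ip = dk.individual_params(MODEL.theta, MODEL.omega, cov, true_eta)
        doses = (dk.DoseEvent("x", 0.0, 500.0, 1.0),)
        times = [0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0]
        obs = tuple(dk.simulate_observations(ip, doses, times, ResidualSpec(1e-12), rng, "x"))
        subj = dk.Subject("x", cov, doses, obs)
        wide = OmegaMatrix(0.5, 0.5, 0.5, 0.5, 0.5)
        eta = dk.empirical_bayes(MODEL.theta, wide, ResidualSpec(1e-4), subj)
        np.testing.assert_allclose(eta, true_eta, atol=1e-4)


class TestShrinkageAndDiagnostics:
    def test_noise_free_population_data_has_zero_residuals(self, rng):
        quiet = dk.FinalModel(
            theta=MODEL.theta,
            omega=ZERO_OMEGA,
            resid=ResidualSpec(1e-9),
        )
        ds = dk.generate_cohort(
            dk.CohortSpec(n_subjects=6, n_crrt=2, missingness=0.0), model=quiet, rng=rng
        )
        prob = FoceiProblem(ds, dk.FINAL_MODEL_SPEC, refs=_published_refs(MODEL.theta))
        p = published_params(MODEL.theta, ZERO_OMEGA, ResidualSpec(0.365))
        diag = dk.diagnostics(prob.evaluate(p))
        np.testing.assert_allclose(diag["pred"], diag["dv"], rtol=1e-6)
        np.testing.assert_allclose(diag["ipred"], diag["dv"], rtol=1e-6)
        assert np.abs(diag["iwres"]).max() < 1e-3

    def test_cwres_calibrated_under_true_model(self):
        ds = dk.generate_cohort(
            dk.CohortSpec(n_subjects=210, n_crrt=90, n_low_dose=10),
            rng=np.random.default_rng(3),
        )
        prob = FoceiProblem(ds, dk.FINAL_MODEL_SPEC, refs=_published_refs(MODEL.theta))
        diag = dk.diagnostics(prob.evaluate(published_params(MODEL.theta, MODEL.omega, MODEL.resid)))
        assert len(diag) > 700
        assert abs(diag["cwres"].mean()) < 0.1

    def test_shrinkage_small_with_rich_data_and_nan_for_zero_omega(self):
        ds = dk.generate_cohort(
            dk.CohortSpec(
                n_subjects=60,
                n_crrt=24,
                missingness=0.0,
                sampling_times=(0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0),
            ),
            rng=np.random.default_rng(4),
        )
        fit = dk.fit_population(ds, dk.FINAL_MODEL_SPEC, fixed={"om_q": 0.0})
        shr = dk.shrinkage(fit)
        # the dominant clearance variability (CRRT group, 22.2% CV) is well
        # individualized under dense sampling
        assert shr["cl_crrt"] < 15.0
        assert np.isnan(shr["q"])
        assert -25.0 < shr["epsilon"] < 100.0


@pytest.fixture(scope="module")
def fits():
    two_comp_data = dk.generate_cohort(
        dk.CohortSpec(n_subjects=40, n_crrt=16, n_low_dose=2),
        rng=np.random.default_rng(5),
    )
    one = dk.fit_population(two_comp_data, dk.ONE_COMPARTMENT_SPEC)
    two = dk.fit_population(two_comp_data, dk.BASE_MODEL_SPEC)
    return one, two


class TestModelMisspecification:
    def test_two_compartment_model_preferred(self, fits):
        one, two = fits
        assert one.ofv - two.ofv > 0

    def test_cwres_trend_reveals_missing_compartment(self, fits):
        one, _ = fits
        diag = dk.diagnostics(one)
        early = diag[diag["time"] <= 1.0]
        assert abs(early["cwres"].mean()) > 0.5
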