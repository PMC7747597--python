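"""Population parameter model: covariate clearances, random effects, residuals."""

import dataclasses

import numpy as np
import pytest

import doripk as dk
from doripk.pop_model import PUBLISHED_FINAL_MODEL as MODEL


def _cov(ccr=62.25, crrt=False, qe=None):
    return dk.CovariateSet(
        ccr=ccr, body_weight=61.5, albumin=2.8, age=61.8, sex="male", crrt=crrt, q_effluent=qe
    )


class TestTypicalClearance:
    def test_reference_ccr_gives_typical_value(self):
        assert dk.typical_clearance(MODEL.theta, _cov(ccr=62.25)) == pytest.approx(3.65)

    def test_low_renal_function(self):
        # 3.65 * (30/62.25)**0.64
        assert dk.typical_clearance(MODEL.theta, _cov(ccr=30.0)) == pytest.approx(2.288, abs=1e-3)

    def test_crrt_reference_with_unit_effluent_flow(self):
        cl = dk.typical_clearance(MODEL.theta, _cov(ccr=52.75, crrt=True, qe=1.0))
        assert cl == pytest.approx(2.49 + 0.919, abs=1e-9)

    def test_strictly_increasing_in_ccr_and_qe(self):
        cls = [dk.typical_clearance(MODEL.theta, _cov(ccr=c)) for c in (20, 40, 60, 80, 100)]
        assert np.all(np.diff(cls) > 0)
        cls_qe = [
            dk.typical_clearance(MODEL.theta, _cov(ccr=50, crrt=True, qe=q))
            for q in (0.6, 1.0, 1.4, 1.8)
        ]
        np.testing.assert_allclose(np.diff(cls_qe), 0.4 * 0.919, rtol=1e-9)

    def test_crrt_body_component_depends_only_on_ccr(self):
        for qe in (0.6, 1.2, 1.8):
            cov = _cov(ccr=45.0, crrt=True, qe=qe)
            body = dk.typical_clearance(MODEL.theta, cov) - dk.crrt_clearance(MODEL.theta, qe)
            assert body == pytest.approx(
                dk.typical_clearance(MODEL.theta, _cov(ccr=45.0, crrt=True, qe=1.0))
                - dk.crrt_clearance(MODEL.theta, 1.0)
            )


class TestCrrtClearance:
    @pytest.mark.parametrize("qe,expected", [(1.0, 0.919), (0.0, 0.0), (1.8, 1.6542)])
    def test_values(self, qe, expected):
        assert dk.crrt_clearance(MODEL.theta, qe) == pytest.approx(expected, abs=1e-9)

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            dk.crrt_clearance(MODEL.theta, -0.1)


class TestIndividualParams:
    def test_zero_etas_reproduce_typical_values(self):
        ip = dk.individual_params(MODEL.theta, MODEL.omega, _cov(ccr=62.25), np.zeros(5))
        assert (ip.cl_total, ip.v1, ip.v2, ip.q) == pytest.approx((3.65, 10.04, 8.13, 3.53))

    def test_eta_v1_doubles_volume(self):
        eta = np.zeros(5)
        eta[2] = np.log(2.0)
        ip = dk.individual_params(MODEL.theta, MODEL.omega, _cov(), eta)
        assert ip.v1 == pytest.approx(20.08)

    def test_machine_clearance_outside_exponential(self):
        # CRRT clearance is added after exp(eta): subtracting it recovers a
        # pure log-normal body clearance
        eta = np.zeros(5)
        eta[1] = 0.5
        cov = _cov(ccr=52.75, crrt=True, qe=1.5)
        ip = dk.individual_params(MODEL.theta, MODEL.omega, cov, eta)
        assert ip.cl_total - 0.919 * 1.5 == pytest.approx(2.49 * np.exp(0.5))

    def test_clearance_cv_matches_omega(self, rng):
        # sample CV of non-CRRT body clearance over 1e5 draws ~ 7.3%
        etas = rng.normal(0.0, MODEL.omega.omega_cl_noncrrt, 100_000)
        cl = 3.65 * np.exp(etas)
        cv = cl.std() / cl.mean()
        assert cv == pytest.approx(0.073, abs=0.003)

    def test_published_model_is_frozen(self):
        with pytest.raises(dataclasses.FrozenInstanceError):
            MODEL.theta.tv_v1 = 1.0


class TestSimulateObservations:
    @pytest.fixture
    def setup(self):
        ip = dk.individual_params(MODEL.theta, MODEL.omega, _cov(), np.zeros(5))
        doses = [dk.DoseEvent("s", 0.0, 500.0, 1.0)]
        return ip, doses

    def test_vanishing_noise_reproduces_predictions(self, setup, rng):
        ip, doses = setup
        times = [1.0, 2.0, 4.0, 8.0]
        obs = dk.simulate_observations(ip, doses, times, dk.ResidualSpec(1e-12), rng)
        pred = dk.concentration_profile(ip, doses, times)
        np.testing.assert_allclose([o.concentration for o in obs], pred, rtol=1e-9)

    def test_seed_reproducibility(self, setup):
        ip, doses = setup
        a = dk.simulate_observations(ip, doses, [1.0, 4.0], MODEL.resid, np.random.default_rng(7))
        b = dk.simulate_observations(ip, doses, [1.0, 4.0], MODEL.resid, np.random.default_rng(7))
        assert [o.concentration for o in a] == [o.concentration for o in b]

    def test_log_scale_sd_matches_sigma(self, setup, rng):
        ip, doses = setup
        vals = [
            dk.simulate_observations(ip, doses, [4.0], MODEL.resid, rng)[0].concentration
            for _ in range(10_000)
        ]
        assert np.std(np.log(vals)) == pytest.approx(0.365, abs=0.01)

    def test_zero_prediction_time_skipped_with_warning(self, setup, rng):
        ip, doses = setup
        with pytest.warns(UserWarning):
            obs = dk.simulate_observations(ip, doses, [0.0, 2.0], MODEL.resid, rng)
        assert len(obs) == 1
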