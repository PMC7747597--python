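"""Virtual-cohort generator: design fidelity and covariate distributions."""

import numpy as np
import pytest

import doripk as dk


class TestDesignFidelity:
    def test_default_design(self, study_cohort):
        ds = study_cohort
        assert ds.n_subjects == 21
        assert sum(s.covariates.crrt for s in ds.subjects) == 9
        doses = [s.doses[0].amount for s in ds.subjects]
        assert doses.count(500.0) == 20 and doses.count(250.0) == 1
        # the single 250 mg dose goes to a non-CRRT subject
        low = next(s for s in ds.subjects if s.doses[0].amount == 250.0)
        assert not low.covariates.crrt
        for s in ds.subjects:
            assert s.doses[0].duration == 1.0
            assert all(o.time in (0.0, 1.0, 2.0, 4.0, 6.0, 8.0) for o in s.observations)

    def test_observation_slots_before_missingness(self, rng):
        ds = dk.generate_cohort(dk.CohortSpec(missingness=0.0), rng=rng)
        assert ds.n_observations == 21 * 6

    def test_missingness_emulates_study_sample_count(self):
        counts = [
            dk.generate_cohort(dk.CohortSpec(), rng=np.random.default_rng(100 + i)).n_observations
            for i in range(30)
        ]
        assert np.mean(counts) == pytest.approx(97.0, abs=3.0)

    def test_empty_cohort(self, rng):
        ds = dk.generate_cohort(dk.CohortSpec(n_subjects=0, n_crrt=0), rng=rng)
        assert ds.n_subjects == 0

    def test_loq_flags_only_below_threshold(self, study_cohort):
        for s in study_cohort.subjects:
            for o in s.observations:
                assert o.below_loq == (o.concentration < 0.5)

    def test_truth_records_match_design(self, rng):
        ds, truth = dk.generate_cohort(dk.CohortSpec(), rng=rng, with_truth=True)
        assert len(truth) == 21
        assert all(t["cl_total"] > 0 for t in truth)


@pytest.fixture(scope="module")
def big():
    spec = dk.CohortSpec(n_subjects=1000, n_crrt=400, n_low_dose=20)
    return spec, dk.generate_cohort(spec, rng=np.random.default_rng(13))


class TestCovariateDistributions:
    def test_means_and_spreads(self, big):
        spec, ds = big
        age = np.array([s.covariates.age for s in ds.subjects])
        bw = np.array([s.covariates.body_weight for s in ds.subjects])
        ccr_non = np.array([s.covariates.ccr for s in ds.subjects if not s.covariates.crrt])
        ccr_crrt = np.array([s.covariates.ccr for s in ds.subjects if s.covariates.crrt])
        # truncation pulls the SD slightly below the nominal value
        assert age.mean() == pytest.approx(spec.age_mean, abs=3 * spec.age_sd / np.sqrt(1000))
        assert bw.mean() == pytest.approx(spec.bw_mean, abs=3 * spec.bw_sd / np.sqrt(1000))
        assert ccr_non.mean() == pytest.approx(spec.ccr_noncrrt_mean, rel=0.05)
        assert ccr_crrt.mean() == pytest.approx(spec.ccr_crrt_mean, rel=0.05)
        assert 0.8 * spec.ccr_noncrrt_sd < ccr_non.std() < 1.05 * spec.ccr_noncrrt_sd

    def test_effluent_flow_within_study_range(self, big):
        _, ds = big
        qes = [s.covariates.q_effluent for s in ds.subjects if s.covariates.crrt]
        assert all(0.6 <= q <= 1.8 for q in qes)

    def test_physiologic_floors(self, big):
        _, ds = big
        assert all(s.covariates.ccr >= 5.0 for s in ds.subjects)
        assert all(s.covariates.body_weight >= 30.0 for s in ds.subjects)


class TestNullCovariate:
    def test_reproducible_and_nondestructive(self, study_cohort):
        a = dk.generate_null_covariate(study_cohort, np.random.default_rng(14))
        b = dk.generate_null_covariate(study_cohort, np.random.default_rng(14))
        va = [s.covariates.extras["noise"] for s in a.subjects]
        vb = [s.covariates.extras["noise"] for s in b.subjects]
        assert va == vb
        for orig, new in zip(study_cohort.subjects, a.subjects):
            assert orig.covariates.ccr == new.covariates.ccr
            assert "noise" not in orig.covariates.extras
            assert len(orig.observations) == len(new.observations)

    def test_independent_of_clearance_by_construction(self):
        rs = []
        for i in range(40):
            rng = np.random.default_rng(200 + i)
            ds, truth = dk.generate_cohort(dk.CohortSpec(), rng=rng, with_truth=True)
            ds = dk.generate_null_covariate(ds, rng)
            noise = np.array([s.covariates.extras["noise"] for s in ds.subjects])
            cl = np.array([t["cl_total"] for t in truth])
            rs.append(abs(np.corrcoef(noise, cl)[0, 1]))
        assert np.mean(rs) < 0.2
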