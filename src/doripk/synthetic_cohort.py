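"""Virtual study cohorts emulating the ICU doripenem trial design.

The generator reproduces the study's structure — 21 subjects of whom 9
receive CRRT, a 1-h infusion of 500 mg (one subject 250 mg), plasma sampling
pre-dose and at 1, 2, 4, 6 and 8 h after the start of the first infusion, an
assay LOQ of 0.5 µg/mL — with covariates drawn from truncated normals
matching the reported demographic means and SDs.  It exists so that
estimation, covariate selection, validation and dosing simulation are
testable without the (undeposited) patient data; serum albumin was not
reported and its distribution here is a synthetic stand-in typical of ICU
patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .pop_model import (
    ETA_NAMES,
    PUBLISHED_FINAL_MODEL,
    FinalModel,
    individual_params,
    simulate_observations,
)
from .study_data import (
    CovariateSet,
    DoseEvent,
    Observation,
    StudyDataset,
    Subject,
)

__all__ = ["CohortSpec", "generate_cohort", "generate_null_covariate"]


@dataclass(frozen=True)
class CohortSpec:
    """Design and covariate distributions of a virtual cohort.

    Defaults reproduce the study conditions: subject counts, dose split,
    nominal sampling times, and demographic means/SDs.  ``missingness`` is
    the probability that any observation slot goes unrecorded; the default
    0.23 makes the expected retained count match the study's 97 samples out
    of 21 x 6 slots.
    """

    n_subjects: int = 21
    n_crrt: int = 9
    dose_mg: float = 500.0
    n_low_dose: int = 1
    low_dose_mg: float = 250.0
    infusion_duration: float = 1.0
    sampling_times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)
    loq: float = 0.5
    age_mean: float = 61.8
    age_sd: float = 18.9
    bw_mean: float = 61.5
    bw_sd: float = 13.6
    ccr_noncrrt_mean: float = 76.0
    ccr_noncrrt_sd: float = 35.8
    ccr_crrt_mean: float = 57.3
    ccr_crrt_sd: float = 26.5
    alb_mean: float = 2.8
    alb_sd: float = 0.6
    qe_low: float = 0.6
    qe_high: float = 1.8
    p_male: float = 18.0 / 21.0
    missingness: float = 0.23

    def __post_init__(self) -> None:
        if self.n_crrt > self.n_subjects:
            raise ValueError("n_crrt cannot exceed n_subjects")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n: int, floor: float) -> np.ndarray:
    """Normal draws truncated to the [1st, 99th] percentiles and floored.

    Truncation plus a physiologic floor keeps degenerate subjects (negative
    weight, near-zero renal function) out of the virtual population.
    """
    lo, hi = mean - 2.3263 * sd, mean + 2.3263 * sd
    out = np.empty(n)
    for i in range(n):
        x = rng.normal(mean, sd)
        while not (lo <= x <= hi):
            x = rng.normal(mean, sd)
        out[i] = x
    return np.maximum(out, floor)


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    model: FinalModel = PUBLISHED_FINAL_MODEL,
    rng: np.random.Generator | None = None,
    with_truth: bool = False,
):
    """Simulate a full study dataset under the population model.

    Returns a :class:`~doripk.study_data.StudyDataset`; with ``with_truth``
    also returns a list of per-subject dicts holding the simulated etas and
    realized structural parameters for parameter-recovery experiments.

    The pre-dose (t = 0) sample is carried as a zero-concentration record
    flagged below the LOQ, matching its structural value under the model.
    """
    rng = np.random.default_rng() if rng is None else rng
    n, n_crrt = spec.n_subjects, spec.n_crrt
    crrt = np.zeros(n, bool)
    crrt[:n_crrt] = True

    age = _truncnorm(rng, spec.age_mean, spec.age_sd, n, floor=18.0)
    bw = _truncnorm(rng, spec.bw_mean, spec.bw_sd, n, floor=30.0)
    alb = _truncnorm(rng, spec.alb_mean, spec.alb_sd, n, floor=1.0)
    ccr = np.where(
        crrt,
        _truncnorm(rng, spec.ccr_crrt_mean, spec.ccr_crrt_sd, n, floor=5.0),
        _truncnorm(rng, spec.ccr_noncrrt_mean, spec.ccr_noncrrt_sd, n, floor=5.0),
    )
    qe = rng.uniform(spec.qe_low, spec.qe_high, n)
    male = rng.random(n) < spec.p_male

    # the low (250 mg) doses go to non-CRRT subjects, as in the study
    dose = np.full(n, spec.dose_mg)
    non_idx = np.flatnonzero(~crrt)
    k_low = min(spec.n_low_dose, len(non_idx))
    if k_low:
        dose[rng.choice(non_idx, size=k_low, replace=False)] = spec.low_dose_mg

    omega_sds = model.omega.sds
    subjects: list[Subject] = []
    truth: list[dict] = []
    for i in range(n):
        sid = f"S{i + 1:02d}"
        cov = CovariateSet(
            ccr=float(ccr[i]),
            body_weight=float(bw[i]),
            albumin=float(alb[i]),
            age=float(age[i]),
            sex="male" if male[i] else "female",
            crrt=bool(crrt[i]),
            q_effluent=float(qe[i]) if crrt[i] else None,
        )
        eta = rng.normal(0.0, omega_sds)
        # only the subject's own clearance-group eta is realized
        eta[0 if crrt[i] else 1] = 0.0
        ip = individual_params(model.theta, model.omega, cov, eta)
        doses = (DoseEvent(sid, 0.0, float(dose[i]), spec.infusion_duration),)
        post_times = [t for t in spec.sampling_times if t > 0]
        obs = simulate_observations(
            ip, doses, post_times, model.resid, rng, subject_id=sid, loq=spec.loq
        )
        if 0.0 in spec.sampling_times:
            obs = [Observation(sid, 0.0, 0.0, below_loq=True)] + obs
        # missingness over all observation slots; always retain at least one
        # post-dose sample so the subject stays informative
        keep = rng.random(len(obs)) >= spec.missingness
        post = [j for j, o in enumerate(obs) if o.time > 0]
        if post and not any(keep[j] for j in post):
            keep[rng.choice(post)] = True
        obs = tuple(o for j, o in enumerate(obs) if keep[j])
        subjects.append(Subject(sid, cov, doses, obs))
        truth.append(
            {
                "subject_id": sid,
                **{f"eta_{nm}": float(e) for nm, e in zip(ETA_NAMES, eta)},
                "cl_total": ip.cl_total,
                "v1": ip.v1,
                "v2": ip.v2,
                "q": ip.q,
            }
        )
    ds = StudyDataset(subjects=tuple(subjects), loq=spec.loq)
    return (ds, truth) if with_truth else ds


def generate_null_covariate(
    ds: StudyDataset, rng: np.random.Generator, name: str = "noise"
) -> StudyDataset:
    """Add a pure-noise covariate, independent of all parameters by construction.

    The noise has the same marginal location and spread as Ccr so that it is
    a fair type-I-error probe for the covariate screening and forward steps.
    Existing columns are untouched.
    """
    ccr = np.array([s.covariates.ccr for s in ds.subjects])
    vals = np.maximum(rng.normal(ccr.mean(), ccr.std() if len(ccr) > 1 else 1.0, len(ds.subjects)), 1.0)
    subjects = []
    for s, v in zip(ds.subjects, vals):
        cov = s.covariates
        extras = dict(cov.extras)
        extras[name] = float(v)
        subjects.append(replace(s, covariates=replace(cov, extras=extras)))
    return StudyDataset(subjects=tuple(subjects), loq=ds.loq)
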