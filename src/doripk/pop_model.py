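"""Population parameter model for doripenem in intensive care.

Fixed effects (theta) describe a typical patient; total clearance is
partitioned into body clearance, a power function of creatinine clearance
(Ccr) normalized to the group median, and an extracorporeal CRRT clearance
equal to the effluent flow rate times the unbound fraction:

    CL_total = 3.65 * (Ccr / 62.25) ** 0.64                     (no CRRT)
    CL_total = 2.49 * (Ccr / 52.75) ** 0.42 + 0.919 * Q_E       (CRRT)

Inter-individual variability is exponential (log-normal) on CL_body, V1, V2
and Q; the machine clearance carries no random effect.  Residual error is
additive on the log-concentration scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pk_core import IndividualParams, concentration_profile
from .study_data import CovariateSet, DoseEvent, Observation, ValidationError, DEFAULT_LOQ

__all__ = [
    "ThetaVector",
    "OmegaMatrix",
    "ResidualSpec",
    "PUBLISHED_FINAL_MODEL",
    "ETA_NAMES",
    "CovariateEffect",
    "ModelSpec",
    "FINAL_MODEL_SPEC",
    "BASE_MODEL_SPEC",
    "NULL_MODEL_SPEC",
    "ONE_COMPARTMENT_SPEC",
    "typical_clearance",
    "typical_body_clearance",
    "crrt_clearance",
    "individual_params",
    "simulate_observations",
]

#: Order of the per-subject random-effect vector.
ETA_NAMES = ("cl_noncrrt", "cl_crrt", "v1", "v2", "q")


@dataclass(frozen=True)
class ThetaVector:
    """Fixed effects of the final covariate model.

    ``tv_cl_*`` are typical body clearances (L/h) at the group reference Ccr;
    ``exp_ccr_*`` the Ccr power exponents; ``fu`` the unbound fraction that
    scales effluent flow into CRRT clearance; volumes in L, ``tv_q`` in L/h.
    """

    tv_cl_noncrrt: float
    exp_ccr_noncrrt: float
    ccr_ref_noncrrt: float
    tv_cl_crrt: float
    exp_ccr_crrt: float
    ccr_ref_crrt: float
    fu: float
    tv_v1: float
    tv_v2: float
    tv_q: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.fu > 1:
            raise ValueError("unbound fraction must be <= 1")


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal inter-individual variability: SDs of the normal etas.

    Reported in the field as %CV = 100 * omega for small omegas.
    """

    omega_cl_noncrrt: float
    omega_cl_crrt: float
    omega_v1: float
    omega_v2: float
    omega_q: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def sds(self) -> np.ndarray:
        return np.array(
            [self.omega_cl_noncrrt, self.omega_cl_crrt, self.omega_v1, self.omega_v2, self.omega_q]
        )


@dataclass(frozen=True)
class ResidualSpec:
    """Additive residual SD on the natural-log concentration scale."""

    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class FinalModel:
    theta: ThetaVector
    omega: OmegaMatrix
    resid: ResidualSpec


#: The published final population model (frozen).
PUBLISHED_FINAL_MODEL = FinalModel(
    theta=ThetaVector(
        tv_cl_noncrrt=3.65,
        exp_ccr_noncrrt=0.64,
        ccr_ref_noncrrt=62.25,
        tv_cl_crrt=2.49,
        exp_ccr_crrt=0.42,
        ccr_ref_crrt=52.75,
        fu=0.919,
        tv_v1=10.04,
        tv_v2=8.13,
        tv_q=3.53,
    ),
    omega=OmegaMatrix(
        omega_cl_noncrrt=0.073,
        omega_cl_crrt=0.222,
        omega_v1=0.132,
        omega_v2=0.242,
        omega_q=0.127,
    ),
    resid=ResidualSpec(sigma=0.365),
)


def crrt_clearance(theta: ThetaVector, q_effluent: float) -> float:
    """Extracorporeal clearance (L/h): effluent flow times the unbound fraction."""
    if q_effluent < 0:
        raise ValueError("effluent flow rate must be >= 0")
    return theta.fu * q_effluent


def typical_body_clearance(theta: ThetaVector, cov: CovariateSet) -> float:
    """Typical body (non-machine) clearance for a patient's covariates."""
    if cov.crrt:
        return theta.tv_cl_crrt * (cov.ccr / theta.ccr_ref_crrt) ** theta.exp_ccr_crrt
    return theta.tv_cl_noncrrt * (cov.ccr / theta.ccr_ref_noncrrt) ** theta.exp_ccr_noncrrt


def typical_clearance(theta: ThetaVector, cov: CovariateSet) -> float:
    """Typical total clearance: body clearance plus CRRT clearance when on CRRT."""
    cl = typical_body_clearance(theta, cov)
    if cov.crrt:
        if cov.q_effluent is None:
            raise ValidationError("CRRT subject requires an effluent flow rate")
        cl += crrt_clearance(theta, cov.q_effluent)
    return cl


def individual_params(
    theta: ThetaVector,
    omega: OmegaMatrix,
    cov: CovariateSet,
    eta: Sequence[float],
) -> IndividualParams:
    """Realize one subject's structural parameters from a 5-vector of etas.

    Etas act multiplicatively (``exp(eta)``) on the typical values; the
    clearance eta used is the CRRT-group one when the subject is on CRRT.
    CRRT clearance is added after the exponential — the machine's clearance
    carries no inter-individual random effect.
    """
    eta = np.asarray(eta, float)
    if eta.shape != (5,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite 5-vector")
    eta_cl = eta[1] if cov.crrt else eta[0]
    cl = typical_body_clearance(theta, cov) * np.exp(eta_cl)
    if cov.crrt:
        if cov.q_effluent is None:
            raise ValidationError("CRRT subject requires an effluent flow rate")
        cl += crrt_clearance(theta, cov.q_effluent)
    return IndividualParams(
        cl_total=float(cl),
        v1=float(theta.tv_v1 * np.exp(eta[2])),
        v2=float(theta.tv_v2 * np.exp(eta[3])),
        q=float(theta.tv_q * np.exp(eta[4])),
    )


def simulate_observations(
    params: IndividualParams,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    resid: ResidualSpec,
    rng: np.random.Generator,
    subject_id: str = "sim",
    loq: float = DEFAULT_LOQ,
) -> list[Observation]:
    """Simulate noisy observations: ``ln C_obs = ln C_pred + eps``.

    Times where the model predicts zero concentration (e.g. pre-dose) are
    skipped with a warning, since log-scale noise is undefined there.
    """
    times = np.asarray(times, float)
    pred = concentration_profile(params, doses, times)
    out: list[Observation] = []
    for t, c in zip(times, pred):
        if c <= 0:
            import warnings

            warnings.warn(f"prediction is zero at t={t}; observation skipped")
            continue
        eps = rng.normal(0.0, resid.sigma)
        c_obs = float(np.exp(np.log(c) + eps))
        out.append(Observation(subject_id, float(t), c_obs, below_loq=c_obs < loq))
    return out


# ---------------------------------------------------------------------------
# Model structure specifications (consumed by the estimation machinery)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateEffect:
    """A power-form covariate effect, ``(x / median)**exponent``, on one parameter.

    ``parameter`` is one of ``cl_body``, ``cl_crrt``, ``v1``, ``v2``, ``q``.
    For ``cl_body`` with split clearance groups, ``per_group`` frees a
    separate exponent (and median) per CRRT group; selection runs use a single
    shared exponent (one degree of freedom per candidate).
    """

    covariate: str
    parameter: str
    per_group: bool = False

    def __post_init__(self) -> None:
        if self.parameter not in ("cl_body", "cl_crrt", "v1", "v2", "q"):
            raise ValueError(f"unknown parameter {self.parameter!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Structural + covariate model description.

    ``crrt_partition`` switches on the CL_total = CL_body + fu*Q_E split;
    ``separate_cl_groups`` gives CRRT and non-CRRT patients their own typical
    body clearance and clearance variability.
    """

    n_compartments: int = 2
    crrt_partition: bool = True
    separate_cl_groups: bool = True
    effects: tuple[CovariateEffect, ...] = ()
    fu: float = 0.919
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        object.__setattr__(self, "effects", tuple(self.effects))


#: Final published structure: Ccr on body clearance, per-group exponent.
FINAL_MODEL_SPEC = ModelSpec(
    effects=(CovariateEffect("ccr", "cl_body", per_group=True),), label="final"
)

#: CRRT-partitioned two-compartment model without covariates.
BASE_MODEL_SPEC = ModelSpec(label="base")

#: Conventional two-compartment model (no CRRT clearance route).
NULL_MODEL_SPEC = ModelSpec(crrt_partition=False, separate_cl_groups=False, label="null")

#: One-compartment comparator used for structural model selection.
ONE_COMPARTMENT_SPEC = ModelSpec(n_compartments=1, label="one-compartment")
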