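"""Two-compartment intravenous-infusion kinetics with central elimination.

Drug enters the central compartment (volume ``v1``) at the infusion rate,
distributes to a peripheral compartment (``v2``) with inter-compartmental
clearance ``q``, and is eliminated from the central compartment with total
clearance ``cl_total``.  The closed-form bi-exponential solution is the
primary path (simulation engines need millions of evaluations); a numeric
ODE integration is kept as an independent verification oracle.

All solvers superpose dose contributions, so irregular and overlapping
regimens work unchanged (rates add under linear kinetics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .study_data import DoseEvent

__all__ = [
    "IndividualParams",
    "MicroConstants",
    "micro_constants",
    "concentration_profile",
    "ode_oracle",
    "profile_matrix",
    "profile_matrix_1c",
]


@dataclass(frozen=True)
class IndividualParams:
    """Realized structural parameters of one subject (L, L/h)."""

    cl_total: float
    v1: float
    v2: float
    q: float

    def __post_init__(self) -> None:
        for name in ("cl_total", "v1", "v2", "q"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class MicroConstants:
    """Rate-constant reparameterization: k10 = CL/V1, k12 = Q/V1, k21 = Q/V2.

    ``alpha``/``beta`` are the macro exponents, the roots of
    ``s**2 - (k10+k12+k21)*s + k10*k21``.
    """

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float


def micro_constants(p: IndividualParams) -> MicroConstants:
    k10 = p.cl_total / p.v1
    k12 = p.q / p.v1
    k21 = p.q / p.v2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return MicroConstants(k10=k10, k12=k12, k21=k21, alpha=alpha, beta=beta)


def profile_matrix(
    cl: np.ndarray,
    v1: np.ndarray,
    v2: np.ndarray,
    q: np.ndarray,
    dose_start: np.ndarray,
    dose_rate: np.ndarray,
    dose_dur: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Vectorized closed-form central concentrations.

    Parameters are shape ``(n,)`` (one row per virtual subject); dose arrays
    are shape ``(n, d)`` (pad unused slots with ``rate = 0``); ``times`` is
    ``(m,)`` shared or ``(n, m)`` per subject.  Returns ``(n, m)`` µg/mL.
    """
    cl, v1, v2, q = (np.asarray(a, float).reshape(-1) for a in (cl, v1, v2, q))
    dose_start = np.atleast_2d(np.asarray(dose_start, float))
    dose_rate = np.atleast_2d(np.asarray(dose_rate, float))
    dose_dur = np.atleast_2d(np.asarray(dose_dur, float))
    times = np.asarray(times, float)
    if times.ndim == 1:
        times = times[None, :]

    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    # the discriminant equals (k10-k21)^2 + k12*(k12 + 2*k10 + 2*k21) >= 0;
    # clamp against cancellation for extreme parameter trials
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 1e-30))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    # bolus coefficients: C_bolus = (D/v1)(A e^-at + B e^-bt), A + B = 1
    A = (alpha - k21) / disc
    B = (k21 - beta) / disc

    tau = times[:, None, :] - dose_start[:, :, None]          # (n, d, m)
    tau_pos = np.maximum(tau, 0.0)
    tau_post = np.maximum(tau - dose_dur[:, :, None], 0.0)
    al = alpha[:, None, None]
    be = beta[:, None, None]
    # guarded against overflow on extreme optimizer trial points; callers
    # treat non-finite output as an invalid trial
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        ea = np.exp(-al * tau_post) - np.exp(-al * tau_pos)
        eb = np.exp(-be * tau_post) - np.exp(-be * tau_pos)
        coef = dose_rate[:, :, None] / v1[:, None, None]
        contrib = coef * (A[:, None, None] * ea / al + B[:, None, None] * eb / be)
    return contrib.sum(axis=1)


def profile_matrix_1c(
    cl: np.ndarray,
    v1: np.ndarray,
    dose_start: np.ndarray,
    dose_rate: np.ndarray,
    dose_dur: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """One-compartment analogue of :func:`profile_matrix` (mono-exponential)."""
    cl = np.asarray(cl, float).reshape(-1)
    v1 = np.asarray(v1, float).reshape(-1)
    dose_start = np.atleast_2d(np.asarray(dose_start, float))
    dose_rate = np.atleast_2d(np.asarray(dose_rate, float))
    dose_dur = np.atleast_2d(np.asarray(dose_dur, float))
    times = np.asarray(times, float)
    if times.ndim == 1:
        times = times[None, :]
    k = (cl / v1)[:, None, None]
    tau = times[:, None, :] - dose_start[:, :, None]
    tau_pos = np.maximum(tau, 0.0)
    tau_post = np.maximum(tau - dose_dur[:, :, None], 0.0)
    e = np.exp(-k * tau_post) - np.exp(-k * tau_pos)
    contrib = dose_rate[:, :, None] / v1[:, None, None] * e / k
    return contrib.sum(axis=1)


def _dose_arrays(doses: Sequence[DoseEvent]):
    if len(doses) == 0:
        return (np.zeros((1, 1)), np.zeros((1, 1)), np.ones((1, 1)))
    start = np.array([[d.start_time for d in doses]])
    rate = np.array([[d.rate for d in doses]])
    dur = np.array([[d.duration for d in doses]])
    return start, rate, dur


def concentration_profile(
    p: IndividualParams, doses: Sequence[DoseEvent], times: Sequence[float]
) -> np.ndarray:
    """Central-compartment concentration (µg/mL) at the requested times.

    Exact piecewise bi-exponential solution; no interpolation is involved.
    """
    t = np.asarray(times, float)
    if np.any(t < 0):
        raise ValueError("negative times are outside the model's domain")
    start, rate, dur = _dose_arrays(doses)
    return profile_matrix(
        np.array([p.cl_total]), np.array([p.v1]), np.array([p.v2]), np.array([p.q]),
        start, rate, dur, t,
    )[0]


def ode_oracle(
    p: IndividualParams,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    full_output: bool = False,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Numerically integrate the compartmental ODE system.

    ``dA1/dt = R(t) - (k10 + k12) A1 + k21 A2``;
    ``dA2/dt = k12 A1 - k21 A2``, with a third state accumulating eliminated
    drug (``k10 A1``) so mass balance can be audited.  Integration is split at
    every infusion start/stop so the piecewise-constant input is exact.

    Returns central concentrations ``A1 / v1``; with ``full_output`` returns
    ``(conc, A1, A2, eliminated)``.
    """
    t = np.asarray(times, float)
    if np.any(t < 0):
        raise ValueError("negative times are outside the model's domain")
    mc = micro_constants(p)

    def rate_at(u: float) -> float:
        return sum(d.rate for d in doses if d.start_time <= u < d.end_time)

    def rhs(u, y):
        a1, a2, _ = y
        return [
            rate_at(u) - (mc.k10 + mc.k12) * a1 + mc.k21 * a2,
            mc.k12 * a1 - mc.k21 * a2,
            mc.k10 * a1,
        ]

    breaks = sorted({0.0, *[d.start_time for d in doses], *[d.end_time for d in doses]})
    t_end = max(float(t.max(initial=0.0)), breaks[-1])
    breaks = [b for b in breaks if b < t_end] + [t_end]

    y = np.zeros(3)
    out = {0.0: y.copy()}
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        t_eval = np.unique(np.concatenate([t[(t > lo) & (t <= hi)], [hi]]))
        sol = solve_ivp(rhs, (lo, hi), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{lo}, {hi}]: {sol.message}")
        for ti, yi in zip(sol.t, sol.y.T):
            out[float(ti)] = yi
        y = sol.y[:, -1]

    states = np.array([out[min(out, key=lambda k: abs(k - ti))] for ti in t])
    conc = states[:, 0] / p.v1
    if full_output:
        return conc, states[:, 0], states[:, 1], states[:, 2]
    return conc
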