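"""FOCE-I estimation of population PK parameters.

The marginal likelihood of each subject's log-concentrations is approximated
by a Laplacian expansion at the conditional mode of the random effects, with
the Gauss–Newton (first-order) Hessian — the first-order conditional
estimation scheme.  With an additive residual model on the log scale the
residual variance does not depend on eta, so the interaction term is included
trivially.  Per subject i with active random-effect dimensions d_i:

    OFV_i = sum_j [ r_ij^2 / sigma^2 + ln(2 pi sigma^2) ]
          + eta_i' O^-1 eta_i + ln det(2 pi O)
          + ln det H_i - d_i ln(2 pi),          H_i = J'J / sigma^2 + O^-1

evaluated at the conditional mode eta_i (the empirical Bayes estimate), where
r_ij = ln DV - ln f and J is the Jacobian of ln f with respect to eta.
OFV = sum_i OFV_i; AIC = OFV + 2 * (number of estimated parameters).

The inner eta optimization runs as a damped Newton iteration batched across
all subjects with numpy; the outer problem optimizes theta/omega/sigma on a
log-transformed scale with L-BFGS-B.  An independent adaptive Gauss–Hermite
quadrature oracle (:func:`marginal_ofv_agq`), built on the scalar public
kinetics path, is provided for verifying the approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize

from . import pk_core
from .pop_model import (
    ETA_NAMES,
    FINAL_MODEL_SPEC,
    ModelSpec,
    OmegaMatrix,
    ResidualSpec,
    ThetaVector,
    individual_params,
)
from .study_data import StudyDataset, Subject, apply_loq_policy

__all__ = [
    "FitResult",
    "FoceiProblem",
    "ofv_focei",
    "fit_population",
    "empirical_bayes",
    "shrinkage",
    "diagnostics",
    "marginal_ofv_agq",
    "published_params",
]

_INNER_TOL = 1e-5
_INNER_MAXIT = 60
_FD_DELTA = 1e-4


class EstimationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Problem construction
# ---------------------------------------------------------------------------


class FoceiProblem:
    """Vectorized FOCE-I objective for one dataset and model structure.

    Below-LOQ observations are excluded from the likelihood (the dataset's
    default policy); observations at or before a subject's first dose start
    are structurally zero under the model and are dropped with a warning.
    """

    def __init__(
        self,
        ds: StudyDataset,
        spec: ModelSpec = FINAL_MODEL_SPEC,
        refs: Mapping[tuple, float] | None = None,
        loq_policy: str = "exclude",
    ):
        ds = apply_loq_policy(ds, loq_policy)
        if ds.n_subjects == 0:
            raise EstimationError("dataset has no subjects")
        self.spec = spec
        self.subject_ids = [s.subject_id for s in ds.subjects]
        self.n = len(ds.subjects)
        self.crrt = np.array([s.covariates.crrt for s in ds.subjects])
        self._separate = spec.separate_cl_groups and 0 < self.crrt.sum() < self.n
        self.group = self.crrt.astype(int) if self._separate else np.zeros(self.n, int)
        self.k = 2 if spec.n_compartments == 1 else 4  # eta dims: cl, v1[, v2, q]

        # --- observation / dose arrays (padded + masked) -------------------
        obs_t, obs_y, dose_s, dose_r, dose_d = [], [], [], [], []
        for s in ds.subjects:
            first = min((d.start_time for d in s.doses), default=0.0)
            kept_t, kept_y = [], []
            for o in s.observations:
                if o.time <= first or o.concentration <= 0:
                    warnings.warn(
                        f"subject {s.subject_id}: observation at t={o.time} has zero "
                        "structural prediction; excluded from the likelihood"
                    )
                    continue
                kept_t.append(o.time)
                kept_y.append(np.log(o.concentration))
            obs_t.append(kept_t)
            obs_y.append(kept_y)
            dose_s.append([d.start_time for d in s.doses])
            dose_r.append([d.rate for d in s.doses])
            dose_d.append([d.duration for d in s.doses])
        m = max(1, max(len(t) for t in obs_t))
        d = max(1, max(len(t) for t in dose_s))
        self.times = np.ones((self.n, m))
        self.ylog = np.zeros((self.n, m))
        self.mask = np.zeros((self.n, m), bool)
        self.dose_start = np.zeros((self.n, d))
        self.dose_rate = np.zeros((self.n, d))
        self.dose_dur = np.ones((self.n, d))
        for i in range(self.n):
            mi = len(obs_t[i])
            self.times[i, :mi] = obs_t[i]
            self.ylog[i, :mi] = obs_y[i]
            self.mask[i, :mi] = True
            di = len(dose_s[i])
            self.dose_start[i, :di] = dose_s[i]
            self.dose_rate[i, :di] = dose_r[i]
            self.dose_dur[i, :di] = dose_d[i]
        self.n_obs = int(self.mask.sum())
        self.m_per_subject = self.mask.sum(axis=1)

        # --- covariates -----------------------------------------------------
        self.qe = np.array(
            [s.covariates.q_effluent if s.covariates.crrt else 0.0 for s in ds.subjects]
        )
        self._cov = {
            name: np.array([s.covariates.value(name) for s in ds.subjects])
            for name in {e.covariate for e in spec.effects}
        }
        self.refs = self._compute_refs(refs)

        # --- parameter layout ----------------------------------------------
        self.cl_groups = ("non", "crrt") if self._separate else ("single",)
        theta_names = [f"tv_cl_{g}" if self._separate else "tv_cl" for g in self.cl_groups]
        theta_names.append("tv_v1")
        if self.k == 4:
            theta_names += ["tv_v2", "tv_q"]
        self._exp_names: dict = {}
        for e in spec.effects:
            if e.parameter == "cl_body" and e.per_group and self._separate:
                names = {g: f"exp_{e.covariate}_{e.parameter}_{g}" for g in self.cl_groups}
            else:
                names = {g: f"exp_{e.covariate}_{e.parameter}" for g in self.cl_groups}
            self._exp_names[e] = names
            theta_names += sorted(set(names.values()))
        omega_names = [f"om_cl_{g}" if self._separate else "om_cl" for g in self.cl_groups]
        omega_names.append("om_v1")
        if self.k == 4:
            omega_names += ["om_v2", "om_q"]
        self.theta_names = theta_names
        self.omega_names = omega_names
        self.param_names = theta_names + omega_names + ["sigma"]
        self._eta_cache = np.zeros((self.n, self.k))

    # -- covariate reference values (medians) -------------------------------

    def _compute_refs(self, refs):
        out = dict(refs or {})
        for e in self.spec.effects:
            x = self._cov[e.covariate]
            if e.parameter == "cl_body" and self._separate:
                for g, sel in (("non", ~self.crrt), ("crrt", self.crrt)):
                    out.setdefault((e.covariate, e.parameter, g), float(np.median(x[sel])))
            elif e.parameter == "cl_crrt":
                sel = self.crrt if self.crrt.any() else np.ones(self.n, bool)
                out.setdefault((e.covariate, e.parameter, None), float(np.median(x[sel])))
            else:
                out.setdefault((e.covariate, e.parameter, None), float(np.median(x)))
        return out

    def _effect_multiplier(self, p: Mapping[str, float], parameter: str) -> np.ndarray:
        mult = np.ones(self.n)
        for e in self.spec.effects:
            if e.parameter != parameter:
                continue
            x = self._cov[e.covariate]
            if e.parameter == "cl_body" and self._separate:
                for g, sel in (("non", ~self.crrt), ("crrt", self.crrt)):
                    ref = self.refs[(e.covariate, e.parameter, g)]
                    expo = p[self._exp_names[e][g]]
                    mult[sel] *= (x[sel] / ref) ** expo
            else:
                ref = self.refs[(e.covariate, e.parameter, None)]
                expo = p[self._exp_names[e][self.cl_groups[0]]]
                mult *= (x / ref) ** expo
        return mult

    # -- structural parameters ----------------------------------------------

    def _structurals(self, p: Mapping[str, float]):
        """Per-subject typical values before eta scaling."""
        tv_cl = np.array([p[f"tv_cl_{g}"] if self._separate else p["tv_cl"] for g in self.cl_groups])
        base_cl = tv_cl[self.group] * self._effect_multiplier(p, "cl_body")
        if self.spec.crrt_partition:
            machine = np.where(self.crrt, self.spec.fu * self.qe, 0.0)
            machine = machine * self._effect_multiplier(p, "cl_crrt")
        else:
            machine = np.zeros(self.n)
        base_v1 = p["tv_v1"] * self._effect_multiplier(p, "v1")
        if self.k == 4:
            base_v2 = p["tv_v2"] * self._effect_multiplier(p, "v2")
            base_q = p["tv_q"] * self._effect_multiplier(p, "q")
        else:
            base_v2 = base_q = None
        return base_cl, machine, base_v1, base_v2, base_q

    def _omega_by_subject(self, p: Mapping[str, float]) -> np.ndarray:
        om_cl = np.array([p[f"om_cl_{g}"] if self._separate else p["om_cl"] for g in self.cl_groups])
        cols = [om_cl[self.group], np.full(self.n, p["om_v1"])]
        if self.k == 4:
            cols += [np.full(self.n, p["om_v2"]), np.full(self.n, p["om_q"])]
        return np.stack(cols, axis=1)

    def _logf(self, base, eta: np.ndarray) -> np.ndarray:
        """Log predictions; ``eta`` may be (n, k) or a stacked (s, n, k) batch."""
        base_cl, machine, base_v1, base_v2, base_q = base
        stacked = eta.ndim == 3
        s = eta.shape[0] if stacked else 1
        eta2 = eta.reshape(-1, self.k)
        rep = lambda a: np.tile(a, (s, 1) if a.ndim == 2 else s)
        cl = rep(base_cl) * np.exp(eta2[:, 0]) + rep(machine)
        v1 = rep(base_v1) * np.exp(eta2[:, 1])
        if self.k == 4:
            v2 = rep(base_v2) * np.exp(eta2[:, 2])
            q = rep(base_q) * np.exp(eta2[:, 3])
            conc = pk_core.profile_matrix(
                cl, v1, v2, q, rep(self.dose_start), rep(self.dose_rate), rep(self.dose_dur),
                rep(self.times),
            )
        else:
            conc = pk_core.profile_matrix_1c(
                cl, v1, rep(self.dose_start), rep(self.dose_rate), rep(self.dose_dur),
                rep(self.times),
            )
        mask = np.tile(self.mask, (s, 1))
        out = np.log(np.where(mask, np.maximum(conc, 1e-300), 1.0))
        return out.reshape(s, self.n, -1) if stacked else out

    # -- inner (conditional-mode) problem ------------------------------------

    def _two_h(self, base, eta, inv_s2, log_s2, iw, active, log_om2):
        r = np.where(self.mask, self.ylog - self._logf(base, eta), 0.0)
        data_part = (r * r).sum(1) * inv_s2 + self.m_per_subject * (np.log(2 * np.pi) + log_s2)
        prior_part = (eta * eta * iw + np.where(active, np.log(2 * np.pi) + log_om2, 0.0)).sum(1)
        return data_part + prior_part

    def _inner(self, base, sigma, om, eta):
        inv_s2 = 1.0 / sigma**2
        log_s2 = 2.0 * np.log(sigma)
        active = om > 1e-12
        with np.errstate(divide="ignore"):
            iw = np.where(active, 1.0 / np.maximum(om, 1e-300) ** 2, 0.0)
            log_om2 = np.where(active, 2.0 * np.log(np.maximum(om, 1e-300)), 0.0)
        eta = np.where(active, eta, 0.0)
        f0 = self._two_h(base, eta, inv_s2, log_s2, iw, active, log_om2)
        J = np.zeros((self.n, self.times.shape[1], self.k))
        for _ in range(_INNER_MAXIT):
            # one stacked evaluation: current eta plus +/- perturbations per dim
            stack = np.tile(eta, (2 * self.k + 1, 1, 1))
            for kk in range(self.k):
                stack[1 + 2 * kk, :, kk] += _FD_DELTA
                stack[2 + 2 * kk, :, kk] -= _FD_DELTA
            lf = self._logf(base, stack)
            r = np.where(self.mask, self.ylog - lf[0], 0.0)
            for kk in range(self.k):
                J[:, :, kk] = (lf[1 + 2 * kk] - lf[2 + 2 * kk]) / (2 * _FD_DELTA)
            J *= self.mask[:, :, None]
            g = -np.einsum("nmk,nm->nk", J, r) * inv_s2 + eta * iw
            g = np.where(active, g, 0.0)
            H = np.einsum("nmj,nmk->njk", J, J) * inv_s2
            H[:, np.arange(self.k), np.arange(self.k)] += iw
            # deactivate dims with zero variability
            for kk in range(self.k):
                off = ~active[:, kk]
                H[off, kk, :] = 0.0
                H[off, :, kk] = 0.0
                H[off, kk, kk] = 1.0
            g = np.nan_to_num(g, nan=0.0, posinf=1e6, neginf=-1e6)
            if np.abs(g).max() < _INNER_TOL:
                break
            H = np.nan_to_num(H, nan=0.0, posinf=1e6, neginf=-1e6)
            # Levenberg damping for safety on ill-conditioned subjects
            step = -np.linalg.solve(H + 1e-10 * np.eye(self.k), g[:, :, None])[:, :, 0]
            step = np.clip(np.nan_to_num(step), -5.0, 5.0)
            t = np.ones(self.n)
            new_eta, new_f = eta, f0
            for _ in range(12):
                trial = eta + t[:, None] * step
                f1 = self._two_h(base, trial, inv_s2, log_s2, iw, active, log_om2)
                ok = f1 <= f0 + 1e-12  # NaN objective counts as a failed trial
                new_eta = np.where(ok[:, None], trial, new_eta)
                new_f = np.where(ok, f1, new_f)
                if ok.all():
                    break
                t = np.where(ok, t, t * 0.5)
            eta, f0 = np.where(active, new_eta, 0.0), new_f
        if not np.isfinite(H).all():
            raise EstimationError("inner Hessian is not finite")
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            raise EstimationError(
                "inner Hessian not positive definite for subject(s) "
                f"{[self.subject_ids[i] for i in np.where(sign <= 0)[0]]}"
            )
        d_active = active.sum(1)
        ofv_i = f0 + logdet - d_active * np.log(2 * np.pi)
        return eta, ofv_i, J, r, active, iw

    # -- public evaluation ----------------------------------------------------

    def ofv(self, p: Mapping[str, float], use_cache: bool = True) -> float:
        """FOCE-I objective function value at the given parameters."""
        base = self._structurals(p)
        om = self._omega_by_subject(p)
        eta0 = self._eta_cache if use_cache else np.zeros((self.n, self.k))
        eta, ofv_i, *_ = self._inner(base, p["sigma"], om, eta0)
        self._eta_cache = eta
        return float(ofv_i.sum())

    def ebes(self, p: Mapping[str, float]) -> np.ndarray:
        """Conditional modes (empirical Bayes estimates), shape (n, k)."""
        base = self._structurals(p)
        om = self._omega_by_subject(p)
        eta, *_ = self._inner(base, p["sigma"], om, np.zeros((self.n, self.k)))
        return eta

    def evaluate(self, p: Mapping[str, float]) -> "FitResult":
        """FitResult at fixed parameters (no estimation): OFV, EBEs, diagnostics."""
        ofv = self.ofv(p, use_cache=False)
        return FitResult(
            spec=self.spec,
            params=dict(p),
            refs=dict(self.refs),
            ofv=ofv,
            aic=ofv,
            n_params=0,
            converged=True,
            ebes=self._eta_cache.copy(),
            subject_ids=list(self.subject_ids),
            crrt=self.crrt.copy(),
            problem=self,
        )

    # -- fitting ---------------------------------------------------------------

    def default_init(self) -> dict[str, float]:
        init = {}
        for name in self.theta_names:
            if name.startswith("tv_cl"):
                init[name] = 3.0
            elif name == "tv_v1":
                init[name] = 10.0
            elif name == "tv_v2":
                init[name] = 8.0
            elif name == "tv_q":
                init[name] = 3.0
            elif name.startswith("exp_"):
                init[name] = 0.3
        for name in self.omega_names:
            init[name] = 0.2
        init["sigma"] = 0.3
        return init

    def fit(
        self,
        init: Mapping[str, float] | None = None,
        fixed: Mapping[str, float] | None = None,
        maxiter: int = 300,
        fd_eps: float = 1e-5,
        ftol: float = 1e-9,
    ) -> "FitResult":
        fixed = dict(fixed or {})
        p0 = self.default_init()
        if init:
            p0.update({k: v for k, v in init.items() if k in p0})
        p0.update(fixed)
        free = [nm for nm in self.param_names if nm not in fixed]

        def to_x(p):
            return np.array(
                [p[nm] if nm.startswith("exp_") else np.log(max(p[nm], 1e-6)) for nm in free]
            )

        def to_p(x):
            p = dict(fixed)
            for nm, v in zip(free, x):
                p[nm] = v if nm.startswith("exp_") else float(np.exp(v))
            return p

        bounds = [
            (-5.0, 5.0) if nm.startswith("exp_") else
            (np.log(1e-3), np.log(3.0)) if nm.startswith(("om_", "sigma")) else
            (np.log(1e-3), np.log(1e4))
            for nm in free
        ]
        self._eta_cache = np.zeros((self.n, self.k))

        def objective(x):
            try:
                return self.ofv(to_p(x))
            except (EstimationError, np.linalg.LinAlgError, FloatingPointError):
                return 1e10

        res = minimize(
            objective,
            to_x(p0),
            method="L-BFGS-B",
            bounds=bounds,
            options={"eps": fd_eps, "maxiter": maxiter, "ftol": ftol, "gtol": 5e-5},
        )
        p_hat = to_p(res.x)
        ofv = self.ofv(p_hat, use_cache=False)
        ebes = self._eta_cache.copy()
        n_params = len(free)
        return FitResult(
            spec=self.spec,
            params=p_hat,
            refs=dict(self.refs),
            ofv=ofv,
            aic=ofv + 2 * n_params,
            n_params=n_params,
            converged=bool(res.success),
            ebes=ebes,
            subject_ids=list(self.subject_ids),
            crrt=self.crrt.copy(),
            problem=self,
        )


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, objective value, and per-subject empirical Bayes estimates.

    ``ebes`` columns follow the engine's eta layout: clearance, V1 and, for
    two-compartment structures, V2 and Q.  The clearance column holds the
    subject's own group eta.
    """

    spec: ModelSpec
    params: dict[str, float]
    refs: dict
    ofv: float
    aic: float
    n_params: int
    converged: bool
    ebes: np.ndarray
    subject_ids: list[str]
    crrt: np.ndarray
    problem: FoceiProblem | None = field(default=None, repr=False)

    @property
    def sigma_hat(self) -> float:
        return self.params["sigma"]

    @property
    def theta_hat(self) -> dict[str, float]:
        return {k: v for k, v in self.params.items() if k.startswith(("tv_", "exp_"))}

    @property
    def omega_hat(self) -> dict[str, float]:
        return {k: v for k, v in self.params.items() if k.startswith("om_")}

    def eta_columns(self) -> tuple[str, ...]:
        return ("cl", "v1") if self.spec.n_compartments == 1 else ("cl", "v1", "v2", "q")

    def ebe_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ebes, columns=[f"eta_{c}" for c in self.eta_columns()])
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "crrt", self.crrt)
        return df

    def individual_parameter(self, name: str) -> np.ndarray:
        """EBE-based individual structural parameter values (e.g. ``cl_body``)."""
        prob = self._require_problem()
        base_cl, machine, base_v1, base_v2, base_q = prob._structurals(self.params)
        eta = self.ebes
        table = {
            "cl_body": base_cl * np.exp(eta[:, 0]),
            "cl_total": base_cl * np.exp(eta[:, 0]) + machine,
            "cl_crrt": machine,
            "v1": base_v1 * np.exp(eta[:, 1]),
        }
        if prob.k == 4:
            table["v2"] = base_v2 * np.exp(eta[:, 2])
            table["q"] = base_q * np.exp(eta[:, 3])
        try:
            return table[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def theta_vector(self) -> ThetaVector:
        """View of a final-structure fit as a published-style ThetaVector."""
        p, refs = self.params, self.refs
        try:
            return ThetaVector(
                tv_cl_noncrrt=p["tv_cl_non"],
                exp_ccr_noncrrt=p.get("exp_ccr_cl_body_non", p.get("exp_ccr_cl_body", 1e-12)),
                ccr_ref_noncrrt=refs[("ccr", "cl_body", "non")],
                tv_cl_crrt=p["tv_cl_crrt"],
                exp_ccr_crrt=p.get("exp_ccr_cl_body_crrt", p.get("exp_ccr_cl_body", 1e-12)),
                ccr_ref_crrt=refs[("ccr", "cl_body", "crrt")],
                fu=self.spec.fu,
                tv_v1=p["tv_v1"],
                tv_v2=p["tv_v2"],
                tv_q=p["tv_q"],
            )
        except KeyError as exc:
            raise ValueError("fit does not have the final-model structure") from exc

    def _require_problem(self) -> FoceiProblem:
        if self.problem is None:
            raise ValueError("FitResult is detached from its estimation problem")
        return self.problem


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def published_params(theta: ThetaVector, omega: OmegaMatrix, resid: ResidualSpec) -> dict[str, float]:
    """Map published-style parameter containers onto the engine's layout."""
    return {
        "tv_cl_non": theta.tv_cl_noncrrt,
        "tv_cl_crrt": theta.tv_cl_crrt,
        "exp_ccr_cl_body_non": theta.exp_ccr_noncrrt,
        "exp_ccr_cl_body_crrt": theta.exp_ccr_crrt,
        "tv_v1": theta.tv_v1,
        "tv_v2": theta.tv_v2,
        "tv_q": theta.tv_q,
        "om_cl_non": omega.omega_cl_noncrrt,
        "om_cl_crrt": omega.omega_cl_crrt,
        "om_v1": omega.omega_v1,
        "om_v2": omega.omega_v2,
        "om_q": omega.omega_q,
        "sigma": resid.sigma,
    }


def _published_refs(theta: ThetaVector) -> dict:
    return {
        ("ccr", "cl_body", "non"): theta.ccr_ref_noncrrt,
        ("ccr", "cl_body", "crrt"): theta.ccr_ref_crrt,
    }


def _single_group_fallback(p: dict[str, float], prob: FoceiProblem, theta: ThetaVector) -> dict[str, float]:
    # dataset may contain only one CRRT group; collapse the published params
    # (and pin the Ccr reference to the published group median, not the data's)
    if prob._separate:
        return p
    crrt_only = prob.crrt.all()
    suffix = "_crrt" if crrt_only else "_non"
    q = dict(p)
    q["tv_cl"] = p[f"tv_cl{suffix}"]
    q["om_cl"] = p[f"om_cl{suffix}"]
    q["exp_ccr_cl_body"] = p[f"exp_ccr_cl_body{suffix}"]
    prob.refs[("ccr", "cl_body", None)] = (
        theta.ccr_ref_crrt if crrt_only else theta.ccr_ref_noncrrt
    )
    return q


def ofv_focei(
    theta: ThetaVector,
    omega: OmegaMatrix,
    sigma: ResidualSpec,
    ds: StudyDataset,
    loq_policy: str = "exclude",
) -> float:
    """FOCE-I objective function value of the final-model structure at fixed parameters."""
    prob = FoceiProblem(ds, FINAL_MODEL_SPEC, refs=_published_refs(theta), loq_policy=loq_policy)
    p = _single_group_fallback(published_params(theta, omega, sigma), prob, theta)
    return prob.ofv(p, use_cache=False)


def fit_population(
    ds: StudyDataset,
    spec: ModelSpec = FINAL_MODEL_SPEC,
    init: Mapping[str, float] | None = None,
    fixed: Mapping[str, float] | None = None,
    refs: Mapping[tuple, float] | None = None,
    **opts,
) -> FitResult:
    """Maximize the FOCE-I approximate marginal likelihood over theta/omega/sigma."""
    prob = FoceiProblem(ds, spec, refs=refs)
    return prob.fit(init=init, fixed=fixed, **opts)


def empirical_bayes(
    theta: ThetaVector,
    omega: OmegaMatrix,
    sigma: ResidualSpec,
    subject: Subject,
    loq: float = 0.5,
) -> np.ndarray:
    """MAP estimate of one subject's etas under fixed population parameters.

    Returns the 5-vector in :data:`~doripk.pop_model.ETA_NAMES` order; the
    clearance slot of the subject's group is filled, the other stays zero.
    """
    ds = StudyDataset(subjects=(subject,), loq=loq)
    prob = FoceiProblem(ds, FINAL_MODEL_SPEC, refs=_published_refs(theta))
    p = _single_group_fallback(published_params(theta, omega, sigma), prob, theta)
    eta4 = prob.ebes(p)[0]
    out = np.zeros(5)
    slot = 1 if subject.covariates.crrt else 0
    out[slot] = eta4[0]
    out[2:5] = eta4[1:4]
    return out


def shrinkage(fit: FitResult) -> dict[str, float]:
    """Eta-shrinkage per random effect and epsilon-shrinkage, in percent.

    ``100 * (1 - SD(EBE)/omega)`` per dimension (clearance split by CRRT
    group) and ``100 * (1 - SD(iWRES))``; dimensions with zero variability
    report ``nan``.
    """
    prob = fit._require_problem()
    out: dict[str, float] = {}

    def shr(ebe_vals, om):
        if om <= 1e-12 or len(ebe_vals) < 2:
            return float("nan")
        return 100.0 * (1.0 - np.std(ebe_vals, ddof=1) / om)

    cl_col = fit.ebes[:, 0]
    if prob._separate:
        out["cl_noncrrt"] = shr(cl_col[~fit.crrt], fit.params["om_cl_non"])
        out["cl_crrt"] = shr(cl_col[fit.crrt], fit.params["om_cl_crrt"])
    else:
        out["cl"] = shr(cl_col, fit.params["om_cl"])
    for j, nm in enumerate(fit.eta_columns()[1:], start=1):
        out[nm] = shr(fit.ebes[:, j], fit.params[f"om_{nm}"])
    diag = diagnostics(fit)
    out["epsilon"] = 100.0 * (1.0 - np.std(diag["iwres"], ddof=1))
    return out


def diagnostics(fit: FitResult, ds: StudyDataset | None = None) -> pd.DataFrame:
    """Per-observation goodness-of-fit quantities: PRED, IPRED, iWRES, CWRES.

    PRED is the population prediction (eta = 0), IPRED the individual
    prediction at the empirical Bayes estimates, iWRES the log-scale residual
    standardized by sigma, and CWRES the conditional weighted residual from
    the FOCE linearization (residual scaled by the marginal covariance
    ``J O J' + sigma^2 I`` evaluated at the conditional mode).
    """
    prob = fit._require_problem()
    p = fit.params
    base = prob._structurals(p)
    om = prob._omega_by_subject(p)
    sigma = p["sigma"]
    eta = fit.ebes
    logf_pop = prob._logf(base, np.zeros_like(eta))
    logf_ind = prob._logf(base, eta)
    # Jacobian at the mode for the linearized marginal covariance
    J = np.zeros((prob.n, prob.times.shape[1], prob.k))
    for kk in range(prob.k):
        ep = eta.copy()
        ep[:, kk] += _FD_DELTA
        em = eta.copy()
        em[:, kk] -= _FD_DELTA
        J[:, :, kk] = (prob._logf(base, ep) - prob._logf(base, em)) / (2 * _FD_DELTA)
    J *= prob.mask[:, :, None]

    rows = []
    for i in range(prob.n):
        sel = prob.mask[i]
        mi = int(sel.sum())
        if mi == 0:
            continue
        Ji = J[i, sel, :]
        r_lin = (prob.ylog[i, sel] - logf_ind[i, sel]) + Ji @ eta[i]
        V = Ji @ np.diag(om[i] ** 2) @ Ji.T + sigma**2 * np.eye(mi)
        L = np.linalg.cholesky(V)
        cwres = solve_triangular(L, r_lin, lower=True)
        iwres = (prob.ylog[i, sel] - logf_ind[i, sel]) / sigma
        for j in range(mi):
            rows.append(
                {
                    "subject_id": prob.subject_ids[i],
                    "time": prob.times[i, sel][j],
                    "dv": float(np.exp(prob.ylog[i, sel][j])),
                    "pred": float(np.exp(logf_pop[i, sel][j])),
                    "ipred": float(np.exp(logf_ind[i, sel][j])),
                    "iwres": float(iwres[j]),
                    "cwres": float(cwres[j]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Independent oracle: adaptive Gauss–Hermite quadrature
# ---------------------------------------------------------------------------


def marginal_ofv_agq(
    theta: ThetaVector,
    omega: OmegaMatrix,
    sigma: ResidualSpec,
    ds: StudyDataset,
    n_nodes: int = 31,
    loq_policy: str = "exclude",
) -> float:
    """-2 log marginal likelihood by adaptive Gauss–Hermite quadrature.

    Deliberately built on the scalar public model path
    (:func:`~doripk.pop_model.individual_params` +
    :func:`~doripk.pk_core.concentration_profile`) with its own mode search,
    so it is independent of the vectorized FOCE-I machinery it verifies.
    Practical for at most 3 active random-effect dimensions per subject.
    """
    ds = apply_loq_policy(ds, loq_policy)
    omega_sds = omega.sds
    total = 0.0
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    for subj in ds.subjects:
        first = min((d.start_time for d in subj.doses), default=0.0)
        obs = [o for o in subj.observations if o.time > first and o.concentration > 0]
        times = np.array([o.time for o in obs])
        ylog = np.log([o.concentration for o in obs])
        slot = 1 if subj.covariates.crrt else 0
        candidate_dims = [slot, 2, 3, 4]
        active = [d for d in candidate_dims if omega_sds[d] > 1e-12]
        if len(active) > 3:
            raise ValueError("quadrature oracle supports at most 3 active eta dimensions")

        def nll(eta_act):
            eta5 = np.zeros(5)
            eta5[active] = eta_act
            ip = individual_params(theta, omega, subj.covariates, eta5)
            pred = pk_core.concentration_profile(ip, subj.doses, times) if len(times) else np.array([])
            r = ylog - np.log(pred) if len(times) else np.array([])
            val = 0.5 * np.sum(r**2) / sigma.sigma**2 + 0.5 * len(r) * np.log(
                2 * np.pi * sigma.sigma**2
            )
            for d, e in zip(active, eta_act):
                val += 0.5 * e**2 / omega_sds[d] ** 2 + 0.5 * np.log(2 * np.pi * omega_sds[d] ** 2)
            return val

        d = len(active)
        if d == 0:
            total += 2.0 * nll(np.zeros(0))
            continue
        res = minimize(nll, np.zeros(d), method="BFGS", options={"gtol": 1e-8})
        mode = res.x
        # FD Hessian at the mode
        h = 1e-4
        H = np.zeros((d, d))
        for a in range(d):
            for b in range(a, d):
                pp = mode.copy(); pp[a] += h; pp[b] += h
                pm = mode.copy(); pm[a] += h; pm[b] -= h
                mp = mode.copy(); mp[a] -= h; mp[b] += h
                mm = mode.copy(); mm[a] -= h; mm[b] -= h
                H[a, b] = H[b, a] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * h * h)
        L = np.linalg.cholesky(np.linalg.inv(H))
        nll0 = nll(mode)
        acc = 0.0
        for idx in product(range(n_nodes), repeat=d):
            z = nodes[list(idx)]
            w = np.prod(weights[list(idx)])
            eta_act = mode + np.sqrt(2.0) * (L @ z)
            acc += w * np.exp(np.minimum(np.sum(z**2) - (nll(eta_act) - nll0), 700.0))
        log_integral = -nll0 + 0.5 * d * np.log(2.0) + np.log(np.abs(np.linalg.det(L))) + np.log(acc)
        total += -2.0 * log_integral
    return float(total)
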