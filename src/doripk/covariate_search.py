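"""Stepwise covariate model building on objective-function-value criteria.

Candidates are power-form effects, ``(covariate / median) ** exponent``, on
structural parameters.  Screening keeps candidates whose covariate correlates
with the corresponding EBE-based individual parameter (|r| above a cutoff)
and discards collinear covariates.  Forward addition tests each screened
candidate one at a time against the base model; a drop in OFV of more than
2.71 (chi-squared, 1 df, p < 0.10) accepts it.  Accepted candidates are then
assembled into a full model — where several passers target the same
parameter, the one with the largest OFV drop enters — and backward
elimination removes any effect whose deletion raises OFV by 3.84 or less
(p < 0.05, 1 df).  Each candidate is tested with a single shared exponent
(one degree of freedom); for body clearance the covariate is re-medianed
within the CRRT and non-CRRT groups separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nlme_fit import FitResult, fit_population
from .pop_model import BASE_MODEL_SPEC, CovariateEffect, ModelSpec
from .study_data import StudyDataset

__all__ = [
    "SelectionConfig",
    "SelectionStep",
    "SelectionTrace",
    "accept_forward",
    "retain_backward",
    "screen_covariates",
    "forward_addition",
    "backward_elimination",
    "stepwise_selection",
    "PUBLISHED_STEPWISE_STEPS",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the stepwise procedure (chi-squared, 1 df)."""

    forward_threshold: float = 2.71
    backward_threshold: float = 3.84
    screen_r: float = 0.6
    candidates: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        if self.forward_threshold <= 0 or self.backward_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.screen_r < 1:
            raise ValueError("screen_r must be in (0, 1)")


def accept_forward(delta_ofv: float, cfg: SelectionConfig = SelectionConfig()) -> bool:
    """Forward rule: accept when OFV drops by more than the p<0.10 threshold."""
    return delta_ofv > cfg.forward_threshold


def retain_backward(delta_ofv: float, cfg: SelectionConfig = SelectionConfig()) -> bool:
    """Backward rule: retain when removal raises OFV by more than the p<0.05 threshold."""
    return delta_ofv > cfg.backward_threshold


#: Published stepwise trace of the ICU doripenem model (OFV drops vs the base
#: model for forward rows; OFV rises on removal from the full model for
#: backward rows), with the printed decisions.
PUBLISHED_STEPWISE_STEPS: tuple[tuple[str, str, float, bool], ...] = (
    ("forward", "Ccr on CL_body", 10.71, True),
    ("forward", "Alb on V1", 0.71, False),
    ("forward", "Alb on V2", -5.53, False),
    ("forward", "Alb on CL_CRRT", 3.45, True),
    ("forward", "BW on CL_body", 7.06, True),
    ("forward", "BW on V1", 3.01, True),
    ("forward", "BW on V2", 0.18, False),
    ("forward", "full model", 12.80, True),
    ("backward", "Ccr on CL_body", 8.05, True),
    ("backward", "Alb on CL_CRRT", 0.92, False),
    ("backward", "BW on V1", 0.91, False),
)


@dataclass(frozen=True)
class SelectionStep:
    label: str
    effects: tuple[CovariateEffect, ...]
    ofv: float
    delta_ofv: float
    reference: str
    decision: str


@dataclass
class SelectionTrace:
    """Ordered record of every stepwise test plus the resulting model."""

    steps: list[SelectionStep] = field(default_factory=list)
    final_spec: ModelSpec | None = None
    final_fit: FitResult | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": s.label,
                    "ofv": s.ofv,
                    "delta_ofv": s.delta_ofv,
                    "vs": s.reference,
                    "decision": s.decision,
                }
                for s in self.steps
            ]
        )


def _effect_label(e: CovariateEffect) -> str:
    return f"{e.covariate} on {e.parameter}"


def screen_covariates(
    base_fit: FitResult,
    ds: StudyDataset,
    candidates: Sequence[CovariateEffect],
    screen_r: float = 0.6,
) -> list[CovariateEffect]:
    """Keep candidates correlated with their target parameter; drop collinear ones.

    Correlations are Pearson r between each covariate and the EBE-based
    individual parameter values of the base fit (the only per-subject
    parameter estimates available).  When two surviving candidates' covariates
    are mutually correlated above the cutoff, the one with the weaker
    parameter correlation is dropped.
    """
    base_fit._require_problem()
    cov_values: dict[str, np.ndarray] = {}
    strength: dict[CovariateEffect, float] = {}
    kept: list[CovariateEffect] = []
    for e in candidates:
        x = np.array([s.covariates.value(e.covariate) for s in ds.subjects])
        cov_values[e.covariate] = x
        if np.std(x) == 0:
            warnings.warn(f"covariate {e.covariate!r} is constant; correlation undefined")
            continue
        y = base_fit.individual_parameter(e.parameter if e.parameter != "cl_crrt" else "cl_body")
        r = float(np.corrcoef(x, y)[0, 1])
        strength[e] = abs(r)
        if abs(r) > screen_r:
            kept.append(e)
    # collinearity: drop the weaker of any over-correlated covariate pair
    kept_sorted = sorted(kept, key=lambda e: -strength[e])
    final: list[CovariateEffect] = []
    for e in kept_sorted:
        clash = any(
            e.covariate != f.covariate
            and abs(np.corrcoef(cov_values[e.covariate], cov_values[f.covariate])[0, 1]) > screen_r
            for f in final
        )
        if not clash:
            final.append(e)
    return [e for e in candidates if e in final]


def _with_effect(spec: ModelSpec, e: CovariateEffect) -> ModelSpec:
    return replace(spec, effects=spec.effects + (e,), label=f"{spec.label}+{_effect_label(e)}")


def forward_addition(
    base_spec: ModelSpec,
    candidates: Sequence[CovariateEffect],
    ds: StudyDataset,
    cfg: SelectionConfig = SelectionConfig(),
    init: Mapping[str, float] | None = None,
) -> SelectionTrace:
    """One-at-a-time forward tests against the base model, then the full model.

    All threshold-passing candidates are pooled; if several pass on the same
    parameter, the largest OFV drop wins its slot in the full model (the
    published full model combines the per-parameter best passers).
    """
    trace = SelectionTrace()
    base_fit = fit_population(ds, base_spec, init=init)
    trace.steps.append(
        SelectionStep("base", base_spec.effects, base_fit.ofv, 0.0, "-", "reference")
    )
    passers: list[tuple[CovariateEffect, float]] = []
    for e in candidates:
        try:
            cand_fit = fit_population(ds, _with_effect(base_spec, e), init=init)
        except Exception as exc:  # non-convergent candidate is recorded, not fatal
            trace.steps.append(
                SelectionStep(_effect_label(e), (e,), np.nan, np.nan, "base", f"rejected ({exc})")
            )
            continue
        delta = base_fit.ofv - cand_fit.ofv
        ok = accept_forward(delta, cfg) and cand_fit.converged
        decision = "accepted" if ok else "rejected"
        if accept_forward(delta, cfg) and not cand_fit.converged:
            decision = "rejected (non-convergent)"
        trace.steps.append(
            SelectionStep(_effect_label(e), (e,), cand_fit.ofv, delta, "base", decision)
        )
        if ok:
            passers.append((e, delta))
    best_per_param: dict[str, tuple[CovariateEffect, float]] = {}
    for e, delta in passers:
        cur = best_per_param.get(e.parameter)
        if cur is None or delta > cur[1]:
            best_per_param[e.parameter] = (e, delta)
    full_effects = tuple(e for e, _ in best_per_param.values())
    full_spec = replace(base_spec, effects=base_spec.effects + full_effects, label="full")
    if full_effects:
        full_fit = fit_population(ds, full_spec, init=init)
        delta = base_fit.ofv - full_fit.ofv
        trace.steps.append(
            SelectionStep(
                "full",
                full_effects,
                full_fit.ofv,
                delta,
                "base",
                "accepted" if accept_forward(delta, cfg) else "rejected",
            )
        )
        trace.final_spec, trace.final_fit = full_spec, full_fit
    else:
        trace.final_spec, trace.final_fit = base_spec, base_fit
    return trace


def backward_elimination(
    full_spec: ModelSpec,
    ds: StudyDataset,
    cfg: SelectionConfig = SelectionConfig(),
    init: Mapping[str, float] | None = None,
    full_fit: FitResult | None = None,
) -> SelectionTrace:
    """Remove effects one at a time; keep only those whose removal costs > 3.84 OFV.

    The least significant removable effect is eliminated and the procedure
    repeats until every remaining effect is significant.
    """
    trace = SelectionTrace()
    spec = full_spec
    fit = full_fit if full_fit is not None else fit_population(ds, spec, init=init)
    while True:
        removable: list[tuple[CovariateEffect, float, FitResult]] = []
        for e in spec.effects:
            reduced = replace(
                spec,
                effects=tuple(x for x in spec.effects if x != e),
                label=f"-{_effect_label(e)}",
            )
            red_fit = fit_population(ds, reduced, init=init)
            delta = red_fit.ofv - fit.ofv
            retained = retain_backward(delta, cfg)
            trace.steps.append(
                SelectionStep(
                    f"- {_effect_label(e)}",
                    (e,),
                    red_fit.ofv,
                    delta,
                    spec.label or "current",
                    "retained" if retained else "eliminated",
                )
            )
            if not retained:
                removable.append((e, delta, red_fit))
        if not removable:
            break
        # drop the least significant effect and iterate
        e, _, red_fit = min(removable, key=lambda t: t[1])
        spec = replace(spec, effects=tuple(x for x in spec.effects if x != e), label=spec.label)
        fit = red_fit
    trace.final_spec, trace.final_fit = spec, fit
    return trace


def stepwise_selection(
    ds: StudyDataset,
    candidates: Sequence[CovariateEffect],
    base_spec: ModelSpec = BASE_MODEL_SPEC,
    cfg: SelectionConfig = SelectionConfig(),
    screen: bool = True,
    init: Mapping[str, float] | None = None,
) -> SelectionTrace:
    """Screen, forward-add, then backward-eliminate; returns the merged trace."""
    if screen:
        base_fit = fit_population(ds, base_spec, init=init)
        candidates = screen_covariates(base_fit, ds, candidates, cfg.screen_r)
    fwd = forward_addition(base_spec, candidates, ds, cfg, init=init)
    bwd = backward_elimination(fwd.final_spec, ds, cfg, init=init, full_fit=fwd.final_fit)
    merged = SelectionTrace(steps=fwd.steps + bwd.steps)
    merged.final_spec, merged.final_fit = bwd.final_spec, bwd.final_fit
    return merged
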