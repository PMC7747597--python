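"""Model validation: subject-level bootstrap and visual predictive check.

The bootstrap resamples subjects with replacement to the original subject
count, refits the model on each replicate, and summarizes converged
replicates by median and 2.5th/97.5th percentiles.  Non-converged replicates
are dropped (and counted), not resampled.

The VPC simulates replicate datasets under the model with the original
design — the same subjects' doses, sampling times and covariates — drawing
fresh etas and residual errors per replicate, then compares the observed
5th/50th/95th concentration percentiles per nominal time bin with the 95%
confidence band of the same percentiles across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nlme_fit import FitResult, fit_population
from .pop_model import FinalModel, PUBLISHED_FINAL_MODEL, individual_params
from .pk_core import concentration_profile
from .study_data import StudyDataset, Subject

__all__ = ["BootstrapSummary", "VpcResult", "bootstrap", "vpc"]


@dataclass
class BootstrapSummary:
    """Replicate-level estimates and their percentile summary."""

    replicates: pd.DataFrame
    summary: pd.DataFrame  # index: parameter; columns: median, ci_lo, ci_hi
    n_requested: int
    n_converged: int


def bootstrap(
    ds: StudyDataset,
    spec,
    n_reps: int,
    rng: np.random.Generator,
    init: Mapping[str, float] | None = None,
    refs: Mapping[tuple, float] | None = None,
    fit_opts: Mapping | None = None,
) -> BootstrapSummary:
    """Nonparametric bootstrap over subjects; refit each resampled dataset.

    ``init`` (typically the original fit's estimates) warm-starts every
    replicate fit.  Covariate reference medians are held at the original
    dataset's values via ``refs`` so replicate estimates stay comparable.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if refs is None:
        from .nlme_fit import FoceiProblem

        refs = FoceiProblem(ds, spec).refs
    n = ds.n_subjects
    rows = []
    n_conv = 0
    for rep in range(n_reps):
        idx = rng.integers(0, n, size=n)
        subjects = []
        for j, i in enumerate(idx):
            s = ds.subjects[i]
            sid = f"B{j:03d}"
            subjects.append(
                replace(
                    s,
                    subject_id=sid,
                    doses=tuple(replace(d, subject_id=sid) for d in s.doses),
                    observations=tuple(replace(o, subject_id=sid) for o in s.observations),
                )
            )
        boot_ds = StudyDataset(subjects=tuple(subjects), loq=ds.loq)
        try:
            fit = fit_population(boot_ds, spec, init=init, refs=refs, **(fit_opts or {}))
        except Exception:
            continue
        if not np.isfinite(fit.ofv):
            continue
        n_conv += 1
        rows.append({"replicate": rep, "converged": fit.converged, **fit.params})
    reps = pd.DataFrame(rows)
    param_cols = [c for c in reps.columns if c not in ("replicate", "converged")]
    summary = pd.DataFrame(
        {
            "median": reps[param_cols].median(),
            "ci_lo": reps[param_cols].quantile(0.025),
            "ci_hi": reps[param_cols].quantile(0.975),
        }
    )
    return BootstrapSummary(
        replicates=reps, summary=summary, n_requested=n_reps, n_converged=n_conv
    )


@dataclass
class VpcResult:
    """Observed percentiles and simulated confidence bands per time bin."""

    table: pd.DataFrame
    n_reps: int
    percentiles: tuple[float, float, float]
    stratified: bool = False

    def coverage(self, which: float = 50.0) -> float:
        """Fraction of bins whose observed percentile lies inside its band."""
        t = self.table
        lo = t[f"sim_p{which:g}_lo"]
        hi = t[f"sim_p{which:g}_hi"]
        obs = t[f"obs_p{which:g}"]
        ok = (obs >= lo) & (obs <= hi)
        return float(ok.mean())


def _simulate_replicate(
    ds: StudyDataset, model: FinalModel, rng: np.random.Generator
) -> list[tuple[str, float, float, bool]]:
    """One replicate: per subject draw etas, simulate at the observed times."""
    out = []
    sds = model.omega.sds
    for s in ds.subjects:
        times = np.array([o.time for o in s.observations if o.time > 0])
        if len(times) == 0:
            continue
        eta = rng.normal(0.0, sds)
        eta[0 if s.covariates.crrt else 1] = 0.0
        ip = individual_params(model.theta, model.omega, s.covariates, eta)
        pred = concentration_profile(ip, s.doses, times)
        eps = rng.normal(0.0, model.resid.sigma, len(times))
        conc = np.exp(np.log(pred) + eps)
        for t, c in zip(times, conc):
            out.append((s.subject_id, float(t), float(c), s.covariates.crrt))
    return out


def vpc(
    ds: StudyDataset,
    model: FinalModel = PUBLISHED_FINAL_MODEL,
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
    stratify_crrt: bool = False,
    band: tuple[float, float] = (2.5, 97.5),
) -> VpcResult:
    """Visual predictive check against the model's simulated percentile bands.

    Bins are the exact nominal post-dose times of the design (the sampling
    schedule is fixed, so no smoothing or binning heuristics are needed).
    Residual error is included: the bands describe observations.
    """
    rng = np.random.default_rng() if rng is None else rng
    obs_rows = [
        (s.subject_id, o.time, o.concentration, s.covariates.crrt)
        for s in ds.subjects
        for o in s.observations
        if o.time > 0 and not o.below_loq
    ]
    obs = pd.DataFrame(obs_rows, columns=["subject_id", "time", "conc", "crrt"])
    sims = []
    for rep in range(n_reps):
        rep_rows = _simulate_replicate(ds, model, rng)
        df = pd.DataFrame(rep_rows, columns=["subject_id", "time", "conc", "crrt"])
        df["replicate"] = rep
        sims.append(df)
    sim = pd.concat(sims, ignore_index=True)

    strata = [True, False] if stratify_crrt else [None]
    rows = []
    for st in strata:
        o = obs if st is None else obs[obs.crrt == st]
        s = sim if st is None else sim[sim.crrt == st]
        for t in sorted(o.time.unique()):
            row = {"time": t}
            if st is not None:
                row["crrt"] = st
            ot = o[o.time == t].conc
            stg = s[s.time == t]
            rep_pcts = stg.groupby("replicate").conc.apply(
                lambda x: pd.Series(np.percentile(x, percentiles), index=list(percentiles))
            ).unstack()
            for p in percentiles:
                row[f"obs_p{p:g}"] = float(np.percentile(ot, p))
                row[f"sim_p{p:g}_lo"] = float(np.percentile(rep_pcts[p], band[0]))
                row[f"sim_p{p:g}_med"] = float(np.percentile(rep_pcts[p], 50.0))
                row[f"sim_p{p:g}_hi"] = float(np.percentile(rep_pcts[p], band[1]))
            rows.append(row)
    return VpcResult(
        table=pd.DataFrame(rows),
        n_reps=n_reps,
        percentiles=percentiles,
        stratified=stratify_crrt,
    )
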