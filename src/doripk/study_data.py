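"""Longitudinal PK study data: domain types, CSV I/O, covariates, LOQ handling.

The dataset layout follows the pharmacometric (NONMEM-like) convention of a
single long table holding both dosing records (``EVID == 1``) and observation
records (``EVID == 0``), one row per event, with subject-constant covariates
repeated on every row.  Times are hours since the start of the first infusion;
amounts are mg; concentrations are total plasma doripenem in µg/mL.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LOQ",
    "DEFAULT_DIALECT",
    "DataFormatError",
    "ValidationError",
    "DoseEvent",
    "Observation",
    "CovariateSet",
    "Subject",
    "StudyDataset",
    "read_dataset",
    "write_dataset",
    "cockcroft_gault",
    "apply_loq_policy",
]

#: Lower limit of quantification of the doripenem HPLC assay, µg/mL.
DEFAULT_LOQ = 0.5

#: Logical field -> CSV column name.  Override entries to read foreign dialects.
DEFAULT_DIALECT: Mapping[str, str] = MappingProxyType(
    {
        "id": "ID",
        "time": "TIME",
        "dv": "DV",
        "amt": "AMT",
        "rate": "RATE",
        "evid": "EVID",
        "crrt": "CRRT",
        "qe": "QE",
        "ccr": "CCR",
        "bw": "BW",
        "alb": "ALB",
        "age": "AGE",
        "sex": "SEX",
    }
)

_MANDATORY = ("id", "time", "dv", "amt", "rate", "evid", "crrt", "qe", "ccr", "bw", "alb", "age", "sex")


class DataFormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


@dataclass(frozen=True)
class DoseEvent:
    """A constant-rate intravenous infusion.

    ``rate`` is derived (amount / duration); overlapping infusions are legal
    and their rates add under the linear kinetic model.
    """

    subject_id: str
    start_time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValidationError(f"dose amount must be positive, got {self.amount}")
        if not self.duration > 0:
            raise ValidationError(f"infusion duration must be positive, got {self.duration}")
        if self.start_time < 0:
            raise ValidationError(f"dose start time must be >= 0, got {self.start_time}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class Observation:
    """A measured total plasma concentration at ``time`` hours post first dose."""

    subject_id: str
    time: float
    concentration: float
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"observation time must be >= 0, got {self.time}")
        if self.concentration < 0:
            raise ValidationError(f"concentration must be >= 0, got {self.concentration}")


@dataclass(frozen=True)
class CovariateSet:
    """Subject-constant covariates.

    ``q_effluent`` (CRRT effluent flow, L/h) is required when ``crrt`` is true
    and ignored otherwise.  ``extras`` holds additional named covariates (used
    e.g. for pure-noise calibration covariates) without widening the schema.
    """

    ccr: float
    body_weight: float
    albumin: float
    age: float
    sex: str
    crrt: bool = False
    q_effluent: float | None = None
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ccr > 0:
            raise ValidationError(f"Ccr must be positive, got {self.ccr}")
        if not self.body_weight > 0:
            raise ValidationError(f"body weight must be positive, got {self.body_weight}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.crrt:
            if self.q_effluent is None or not self.q_effluent > 0:
                raise ValidationError(
                    "CRRT subject requires a positive effluent flow rate Q_E"
                )
        object.__setattr__(self, "extras", dict(self.extras))

    def value(self, name: str) -> float:
        """Look up a covariate by logical name (``ccr``/``bw``/``alb``/``age``/``qe`` or an extra)."""
        builtin = {
            "ccr": self.ccr,
            "bw": self.body_weight,
            "alb": self.albumin,
            "age": self.age,
            "qe": float("nan") if self.q_effluent is None else self.q_effluent,
        }
        if name in builtin:
            return builtin[name]
        try:
            return self.extras[name]
        except KeyError:
            raise KeyError(f"unknown covariate {name!r}") from None


@dataclass(frozen=True)
class Subject:
    subject_id: str
    covariates: CovariateSet
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))


@dataclass(frozen=True)
class StudyDataset:
    """All subjects of one study plus the assay LOQ."""

    subjects: tuple[Subject, ...]
    loq: float = DEFAULT_LOQ

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject ids must be unique")
        for s in self.subjects:
            if not s.doses and s.observations:
                raise ValidationError(f"subject {s.subject_id} has observations but no dose")
            first = min((d.start_time for d in s.doses), default=math.inf)
            for o in s.observations:
                if o.time < first:
                    raise ValidationError(
                        f"subject {s.subject_id}: observation at t={o.time} precedes first dose"
                    )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def cockcroft_gault(age: float, body_weight: float, serum_creatinine: float, sex: str) -> float:
    """Creatinine clearance (mL/min) by the Cockcroft–Gault formula.

    ``((140 - age) * weight) / (72 * Scr)``, multiplied by 0.85 for females.
    """
    if serum_creatinine <= 0:
        raise ValueError("serum creatinine must be positive")
    if age <= 0 or body_weight <= 0:
        raise ValueError("age and body weight must be positive")
    sex = {"m": "male", "f": "female"}.get(sex.lower(), sex.lower())
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be male/female, got {sex!r}")
    ccr = (140.0 - age) * body_weight / (72.0 * serum_creatinine)
    if sex == "female":
        ccr *= 0.85
    return ccr


def apply_loq_policy(ds: StudyDataset, policy: str = "exclude") -> StudyDataset:
    """Return a copy of ``ds`` with below-LOQ observations handled.

    ``exclude`` drops them (the default, minimal-assumption choice);
    ``replace_half_loq`` substitutes LOQ/2 for sensitivity analysis.
    """
    if policy not in ("exclude", "replace_half_loq"):
        raise ValueError(f"unknown LOQ policy {policy!r}")
    new_subjects = []
    for s in ds.subjects:
        if policy == "exclude":
            obs = tuple(o for o in s.observations if not o.below_loq)
        else:
            obs = tuple(
                replace(o, concentration=ds.loq / 2.0) if o.below_loq else o
                for o in s.observations
            )
        new_subjects.append(replace(s, observations=obs))
    return StudyDataset(subjects=tuple(new_subjects), loq=ds.loq)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _resolve_dialect(dialect: Mapping[str, str] | None) -> dict[str, str]:
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    return d


def read_dataset(
    path,
    dialect: Mapping[str, str] | None = None,
    loq: float = DEFAULT_LOQ,
) -> StudyDataset:
    """Read a long-format dosing/observation CSV into a :class:`StudyDataset`.

    Columns beyond the dialect's mapped ones are treated as extra per-subject
    covariates (taken from each subject's first row).
    """
    d = _resolve_dialect(dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [d[k] for k in _MANDATORY if d[k] not in df.columns]
    if missing:
        raise DataFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    known = set(d.values())
    extra_cols = [c for c in df.columns if c not in known]

    subjects: list[Subject] = []
    for sid, g in df.groupby(d["id"], sort=False):
        sid = str(sid)
        first = g.iloc[0]
        crrt = bool(int(first[d["crrt"]]))
        qe = first[d["qe"]]
        if crrt and (pd.isna(qe) or not float(qe) > 0):
            raise ValidationError(f"CRRT subject {sid} lacks a positive Q_E")
        sex_raw = str(first[d["sex"]]).strip().lower()
        sex = {"m": "male", "f": "female", "male": "male", "female": "female"}.get(sex_raw)
        if sex is None:
            raise DataFormatError(f"subject {sid}: unrecognized sex {sex_raw!r}")
        cov = CovariateSet(
            ccr=float(first[d["ccr"]]),
            body_weight=float(first[d["bw"]]),
            albumin=float(first[d["alb"]]),
            age=float(first[d["age"]]),
            sex=sex,
            crrt=crrt,
            q_effluent=None if pd.isna(qe) else float(qe),
            extras={c: float(first[c]) for c in extra_cols},
        )
        doses, obs = [], []
        for _, row in g.iterrows():
            t = float(row[d["time"]])
            if t < 0:
                raise ValidationError(f"subject {sid}: negative event time {t}")
            if int(row[d["evid"]]) == 1:
                amt, rate = float(row[d["amt"]]), float(row[d["rate"]])
                doses.append(DoseEvent(sid, start_time=t, amount=amt, duration=amt / rate))
            else:
                dv = float(row[d["dv"]])
                obs.append(Observation(sid, time=t, concentration=dv, below_loq=dv < loq))
        subjects.append(Subject(sid, cov, tuple(doses), tuple(obs)))
    return StudyDataset(subjects=tuple(subjects), loq=loq)


def write_dataset(ds: StudyDataset, path) -> str:
    """Write ``ds`` as a long-format CSV round-trippable by :func:`read_dataset`."""
    d = dict(DEFAULT_DIALECT)
    extra_names: list[str] = []
    for s in ds.subjects:
        for k in s.covariates.extras:
            if k not in extra_names:
                extra_names.append(k)
    rows = []
    for s in ds.subjects:
        c = s.covariates
        common = {
            d["id"]: s.subject_id,
            d["crrt"]: int(c.crrt),
            d["qe"]: c.q_effluent if c.crrt else np.nan,
            d["ccr"]: c.ccr,
            d["bw"]: c.body_weight,
            d["alb"]: c.albumin,
            d["age"]: c.age,
            d["sex"]: "M" if c.sex == "male" else "F",
            **{k: c.extras.get(k, np.nan) for k in extra_names},
        }
        for dose in sorted(s.doses, key=lambda x: x.start_time):
            rows.append(
                {
                    **common,
                    d["time"]: dose.start_time,
                    d["dv"]: np.nan,
                    d["amt"]: dose.amount,
                    d["rate"]: dose.rate,
                    d["evid"]: 1,
                }
            )
        for o in sorted(s.observations, key=lambda x: x.time):
            rows.append(
                {
                    **common,
                    d["time"]: o.time,
                    d["dv"]: o.concentration,
                    d["amt"]: np.nan,
                    d["rate"]: np.nan,
                    d["evid"]: 0,
                }
            )
    columns = [d[k] for k in ("id", "time", "dv", "amt", "rate", "evid", "crrt", "qe", "ccr", "bw", "alb", "age", "sex")] + extra_names
    df = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    df.to_csv(path, index=False)
    return str(path)
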