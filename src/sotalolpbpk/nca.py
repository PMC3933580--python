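"""Noncompartmental analysis of observed and predicted profiles.

The rules mirror the evaluation pipeline's conventions exactly: AUC_last is
the linear trapezoid from the first to the last sampled point with no
extrapolation, Cmax/tmax are the observed maximum (ties broken to the
earliest time), and ke is the negated least-squares slope of the natural
log of the last three concentrations.  Pediatric profiles observed over
less than 10 h are ineligible for ke.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pbpk_core import DoseEvent

#: minimum observation span (h) for ke eligibility in children
PEDIATRIC_KE_MIN_DURATION = 10.0
ADULT_AGE = 18.0


@dataclass
class ConcentrationTimeProfile:
    """One observed or predicted plasma concentration series."""

    subject_id: str
    times: np.ndarray           # h
    concentrations: np.ndarray  # mg/L
    dose: DoseEvent | None = None
    age: float | None = None    # years; None => treated as adult

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def is_pediatric(self) -> bool:
        return self.age is not None and self.age < ADULT_AGE


@dataclass
class NCAMetrics:
    auc_last: float
    cmax: float
    tmax: float
    ke: float | None = None
    ke_ineligible_reason: str | None = None
    cl_over_f: float | None = None

    def as_dict(self) -> dict:
        return {"auc_last": self.auc_last, "cmax": self.cmax,
                "tmax": self.tmax, "ke": self.ke, "cl_over_f": self.cl_over_f}


def auc_last(profile: ConcentrationTimeProfile) -> float:
    """Linear-trapezoid AUC from first to last sampled point (mg·h/L)."""
    if len(profile.times) < 2:
        raise ValueError("AUC requires at least two concentration points")
    return float(np.trapezoid(profile.concentrations, profile.times))


def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Maximum observed concentration and its time (ties -> earliest)."""
    if len(profile.times) < 1:
        raise ValueError("empty profile")
    i = int(np.argmax(profile.concentrations))  # argmax returns first maximum
    return float(profile.concentrations[i]), float(profile.times[i])


def ke_last3(profile: ConcentrationTimeProfile) -> tuple[float | None, str | None]:
    """Elimination-rate constant from the last three log concentrations.

    Returns ``(ke, None)`` or ``(None, reason)`` when the profile is
    ineligible: fewer than three points, non-positive tail concentrations,
    a non-declining tail, or a pediatric profile observed < 10 h.
    """
    t, c = profile.times, profile.concentrations
    if len(t) < 3:
        return None, "fewer than 3 concentration points"
    if profile.is_pediatric and profile.duration < PEDIATRIC_KE_MIN_DURATION:
        return None, (f"pediatric profile observed over {profile.duration:g} h "
                      f"< {PEDIATRIC_KE_MIN_DURATION:g} h")
    tail_t, tail_c = t[-3:], c[-3:]
    if np.any(tail_c <= 0):
        return None, "non-positive concentration in the terminal points"
    slope = np.polyfit(tail_t, np.log(tail_c), 1)[0]
    if slope >= 0:
        return None, "terminal concentrations not declining"
    return float(-slope), None


def nca_metrics(profile: ConcentrationTimeProfile) -> NCAMetrics:
    """All noncompartmental parameters for one profile."""
    auc = auc_last(profile)
    cmax, tmax = cmax_tmax(profile)
    ke, reason = ke_last3(profile)
    cl_over_f = None
    if profile.dose is not None and ke is not None and auc > 0:
        # AUC to infinity only for CL/F; the Obs/Pred pipeline uses AUC_last
        auc_inf = auc + profile.concentrations[-1] / ke
        cl_over_f = profile.dose.amount / auc_inf
    return NCAMetrics(auc_last=auc, cmax=cmax, tmax=tmax, ke=ke,
                      ke_ineligible_reason=reason, cl_over_f=cl_over_f)


# ---------------------------------------------------------------- I/O

def read_profiles_csv(path) -> list[ConcentrationTimeProfile]:
    """Read profiles from a long-format CSV (subject_id, time_h, conc_mg_l[, age_years])."""
    df = pd.read_csv(path)
    required = {"subject_id", "time_h", "conc_mg_l"}
    if not required.issubset(df.columns):
        raise ValueError(f"profile CSV must have columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_h")
        age = float(grp["age_years"].iloc[0]) if "age_years" in grp else None
        out.append(ConcentrationTimeProfile(
            subject_id=str(sid), times=grp["time_h"].to_numpy(),
            concentrations=grp["conc_mg_l"].to_numpy(), age=age))
    return out


def write_profiles_csv(profiles, path) -> None:
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            row = {"subject_id": p.subject_id, "time_h": t, "conc_mg_l": c}
            if p.age is not None:
                row["age_years"] = p.age
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def nca_table(profiles) -> pd.DataFrame:
    """NCA metrics for a set of profiles as a tidy table."""
    rows = []
    for p in profiles:
        m = nca_metrics(p)
        rows.append({"subject_id": p.subject_id, **m.as_dict(),
                     "ke_ineligible_reason": m.ke_ineligible_reason})
    return pd.DataFrame(rows)
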