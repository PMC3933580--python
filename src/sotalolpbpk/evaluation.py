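"""Predictive-performance statistics for observed vs predicted profiles.

Point-level accuracy uses the percentage error PE = (Cpred - Cobs)/Cobs x
100% and its absolute value APE, summarized as medians (MDPE, MDAPE) with
nonparametric bootstrap confidence intervals.  Parameter-level performance
uses per-subject observed/predicted ratios of the NCA metrics, summarized
as arithmetic means with percentile bootstrap CIs, classified against the
twofold range [0.5, 2] and the bioequivalence-style band [0.8, 1.25], and
stratified by pediatric age group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nca import ConcentrationTimeProfile

DEFAULT_N_BOOTSTRAP = 10_000

#: pediatric age-group bounds in years: [lo, hi) except neonates [0, 28 d]
_DAY = 1.0 / 365.25
AGE_GROUPS = (
    ("neonates", 0.0, 29 * _DAY),
    ("infants", 29 * _DAY, 1.0),
    ("toddlers", 1.0, 2.0),
    ("preschool", 2.0, 6.0),
    ("school", 6.0, 12.0),
    ("adolescents", 12.0, 18.0),
    ("adults", 18.0, np.inf),
)
AGE_GROUP_LABELS = tuple(g[0] for g in AGE_GROUPS)


def assign_age_group(age: float) -> str:
    """Age-group label; neonates are 0-28 days inclusive, adults >= 18 y."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if age * 365.25 <= 28.0:
        return "neonates"
    for label, lo, hi in AGE_GROUPS[1:]:
        if lo <= age < hi:
            return label
    return "adults"


@dataclass
class ErrorMetrics:
    mdpe: float                    # %
    mdape: float                   # %
    mdpe_ci: tuple[float, float]
    mdape_ci: tuple[float, float]
    n_points: int


@dataclass
class RatioSummary:
    parameter: str
    ratios: np.ndarray = field(repr=False)
    mean_ratio: float = None
    ci_low: float = None
    ci_high: float = None
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP
    within_twofold: bool = None
    age_group: str | None = None


def percentage_errors(pred_times, pred_conc, obs: ConcentrationTimeProfile
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Signed PE and APE (%) at each observed point.

    The dense predicted curve is linearly interpolated onto the observed
    times; observed zeros are excluded with a warning.
    """
    pred_times = np.asarray(pred_times, float)
    pred_conc = np.asarray(pred_conc, float)
    c_pred = np.interp(obs.times, pred_times, pred_conc)
    mask = obs.concentrations > 0
    if not mask.all():
        warnings.warn(
            f"{(~mask).sum()} observed zero-concentration point(s) excluded "
            f"from PE for subject {obs.subject_id}", stacklevel=2)
    pe = (c_pred[mask] - obs.concentrations[mask]) / obs.concentrations[mask] * 100.0
    return pe, np.abs(pe)


def _bootstrap_stat(values: np.ndarray, stat, n_bootstrap: int,
                    rng: np.random.Generator,
                    alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI of ``stat`` over resamples of ``values``."""
    n = len(values)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    boot = stat(values[idx], axis=1)
    return (float(np.percentile(boot, 100 * alpha / 2)),
            float(np.percentile(boot, 100 * (1 - alpha / 2))))


def mdpe_mdape(point_errors, n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
               seed: int | np.random.Generator | None = None) -> ErrorMetrics:
    """Median PE and median APE (%) with percentile bootstrap 95% CIs."""
    pe = np.asarray(point_errors, float)
    if pe.size == 0:
        raise ValueError("at least one percentage-error point is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ape = np.abs(pe)
    mdpe = float(np.median(pe))
    mdape = float(np.median(ape))
    mdpe_ci = _bootstrap_stat(pe, np.median, n_bootstrap, rng)
    mdape_ci = _bootstrap_stat(ape, np.median, n_bootstrap, rng)
    return ErrorMetrics(mdpe=mdpe, mdape=mdape, mdpe_ci=mdpe_ci,
                        mdape_ci=mdape_ci, n_points=pe.size)


def ratio_summary(obs_metrics: dict, pred_metrics: dict, parameter: str,
                  n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
                  seed: int | np.random.Generator | None = None,
                  mean: str = "arithmetic",
                  age_group: str | None = None) -> RatioSummary:
    """Obs/Pred ratio summary for one NCA parameter over matched subjects.

    ``obs_metrics`` and ``pred_metrics`` map subject_id -> NCAMetrics (or
    dict); subjects lacking the parameter on either side (e.g. ke-ineligible
    profiles) are dropped pairwise.  The mean is arithmetic by default
    (``mean='geometric'`` available) with a percentile bootstrap 95% CI.
    """
    obs_ids, pred_ids = set(obs_metrics), set(pred_metrics)
    if obs_ids != pred_ids:
        raise ValueError(
            "observed and predicted subject sets differ: "
            f"only-observed={sorted(obs_ids - pred_ids)}, "
            f"only-predicted={sorted(pred_ids - obs_ids)}")

    def get(m, p):
        return m.get(p) if isinstance(m, dict) else getattr(m, p)

    ratios = []
    for sid in sorted(obs_ids):
        o, p = get(obs_metrics[sid], parameter), get(pred_metrics[sid], parameter)
        if o is None or p is None:
            continue
        if p <= 0:
            raise ValueError(f"non-positive predicted {parameter} for {sid}")
        ratios.append(o / p)
    ratios = np.asarray(ratios, float)
    if ratios.size == 0:
        raise ValueError(f"no subjects with both observed and predicted {parameter}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mean == "arithmetic":
        center, stat = float(np.mean(ratios)), np.mean
    elif mean == "geometric":
        center = float(np.exp(np.mean(np.log(ratios))))
        stat = lambda x, axis: np.exp(np.mean(np.log(x), axis=axis))
    else:
        raise ValueError(f"unknown mean {mean!r}")
    ci_low, ci_high = _bootstrap_stat(ratios, stat, n_bootstrap, rng)
    return RatioSummary(
        parameter=parameter, ratios=ratios, mean_ratio=center,
        ci_low=ci_low, ci_high=ci_high, n_bootstrap=n_bootstrap,
        within_twofold=bool(0.5 <= center <= 2.0), age_group=age_group)


def range_fraction(ratios, lo: float = 0.8, hi: float = 1.25) -> float:
    """Fraction of ratios inside the closed interval [lo, hi]."""
    r = np.asarray(ratios, float)
    if r.size == 0:
        raise ValueError("ratios must be non-empty")
    return float(np.mean((r >= lo) & (r <= hi)))


def summaries_by_group(subject_ages: dict, obs_metrics: dict, pred_metrics: dict,
                       parameters=("auc_last", "cmax", "tmax", "ke"),
                       n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
                       seed: int | np.random.Generator | None = None
                       ) -> pd.DataFrame:
    """Per-age-group RatioSummary table over all subjects and parameters."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups: dict[str, list] = {}
    for sid, age in subject_ages.items():
        groups.setdefault(assign_age_group(age), []).append(sid)
    rows = []
    for label in AGE_GROUP_LABELS:
        sids = groups.get(label)
        if not sids:
            continue
        for param in parameters:
            try:
                s = ratio_summary(
                    {i: obs_metrics[i] for i in sids},
                    {i: pred_metrics[i] for i in sids},
                    param, n_bootstrap=n_bootstrap, seed=rng,
                    age_group=label)
            except ValueError:
                continue  # e.g. no ke-eligible subjects in the group
            rows.append({"age_group": label, "parameter": param,
                         "mean_ratio": s.mean_ratio, "ci_low": s.ci_low,
                         "ci_high": s.ci_high, "n": len(s.ratios),
                         "within_twofold": s.within_twofold})
    return pd.DataFrame(rows)
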