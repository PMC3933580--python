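"""Virtual-population and virtual-twin simulation.

Inter-individual variability enters through three drug-relevant parameters:
clearance (multiplier on the ontogeny-scaled individual clearance), gastric
emptying time and small-intestinal transit time.  The default variability
set is the explicitly parameterized one: CL lognormal with geometric SD 1.3,
GET uniform 0.2-1.9 h in adults and 0.2-2.1 h in children, SITT normal
4 +/- 1 h truncated at zero.  An alternative set (CL 30% CV, GET 38% CV,
SITT Weibull alpha 2.92 / beta 4.04) is available via
:func:`alternative_variability`.

Adult populations are compared through their MEAN concentration curve;
virtual twins of a child (same age, sex and dosing, resampled weight and
height) are compared through their MEDIAN curve.  Pediatric dosing is the
reported mg/kg/day divided into two daily doses (q12h) simulated to day 5,
with the last dosing interval taken as the steady-state profile; the
linearity of the model lets the multi-dose curve be built by superposition
of a single-dose simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import distribution, ontogeny, physiology
from .absorption import AbsorptionSettings
from .nca import ConcentrationTimeProfile
from .pbpk_core import DoseEvent, build_model, simulate

#: twice-daily regimen simulated to day 5; the last interval is the profile
PEDIATRIC_DOSES_PER_DAY = 2
PEDIATRIC_STEADY_STATE_DAYS = 5


@dataclass(frozen=True)
class VariabilitySpec:
    """Distribution choices for CL, GET and SITT.

    Distributions are tagged tuples:
      CL: ``("lognormal_gsd", gsd)`` | ``("normal_cv", cv)`` | ``("fixed",)``
      GET: ``("uniform", lo, hi)`` | ``("normal_cv", cv)`` | ``("fixed",)``
      SITT: ``("truncated_normal", mean, sd)`` | ``("weibull", alpha, beta)``
            | ``("fixed",)``
    ``get_distribution_child`` replaces the GET distribution for subjects
    younger than 18 years.
    """

    cl_distribution: tuple = ("lognormal_gsd", 1.3)
    get_distribution: tuple = ("uniform", 0.2, 1.9)
    get_distribution_child: tuple | None = ("uniform", 0.2, 2.1)
    sitt_distribution: tuple = ("truncated_normal", 4.0, 1.0)

    def __post_init__(self):
        for dist in (self.cl_distribution, self.get_distribution,
                     self.sitt_distribution):
            if not dist or dist[0] not in (
                    "lognormal_gsd", "normal_cv", "uniform",
                    "truncated_normal", "weibull", "fixed"):
                raise ValueError(f"unknown distribution tag in {dist!r}")
            if any(p <= 0 for p in dist[1:]):
                raise ValueError(f"distribution parameters must be > 0: {dist!r}")
        if self.get_distribution[0] == "uniform" and \
                self.get_distribution[1] >= self.get_distribution[2]:
            raise ValueError("uniform bounds must be ordered")


def fixed_variability() -> VariabilitySpec:
    """No inter-individual variability (deterministic population)."""
    return VariabilitySpec(cl_distribution=("fixed",),
                           get_distribution=("fixed",),
                           get_distribution_child=None,
                           sitt_distribution=("fixed",))


def alternative_variability() -> VariabilitySpec:
    """The CV/Weibull variability set of the first software tool."""
    return VariabilitySpec(cl_distribution=("normal_cv", 0.30),
                           get_distribution=("normal_cv", 0.38),
                           get_distribution_child=None,
                           sitt_distribution=("weibull", 2.92, 4.04))


def _draw(dist: tuple, n: int, rng: np.random.Generator,
          mean_value: float) -> np.ndarray:
    tag = dist[0]
    if tag == "fixed":
        return np.full(n, mean_value)
    if tag == "lognormal_gsd":
        return mean_value * np.exp(rng.normal(0.0, math.log(dist[1]), n))
    if tag == "normal_cv":
        x = rng.normal(mean_value, dist[1] * mean_value, n)
        return np.clip(x, 0.05 * mean_value, None)  # truncate at +0 support
    if tag == "uniform":
        return rng.uniform(dist[1], dist[2], n)
    if tag == "truncated_normal":
        x = rng.normal(dist[1], dist[2], n)
        while np.any(x <= 0):
            bad = x <= 0
            x[bad] = rng.normal(dist[1], dist[2], bad.sum())
        return x
    if tag == "weibull":
        return dist[2] * rng.weibull(dist[1], n)
    raise ValueError(f"unknown distribution {dist!r}")


def sample_variability(n: int, spec: VariabilitySpec,
                       seed: int | np.random.Generator | None = None,
                       pediatric: bool = False):
    """Draw n (CL multiplier, GET h, SITT h) triples."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    get_dist = spec.get_distribution
    if pediatric and spec.get_distribution_child is not None:
        get_dist = spec.get_distribution_child
    cl_mult = _draw(spec.cl_distribution, n, rng, 1.0)
    get = _draw(get_dist, n, rng, 0.5)
    sitt = _draw(spec.sitt_distribution, n, rng, 4.0)
    return cl_mult, get, sitt


@dataclass
class PopulationResult:
    """Per-subject curves on a common grid plus pointwise summaries."""

    times: np.ndarray
    per_subject: np.ndarray            # shape (n_subjects, n_times)
    summary_mean: np.ndarray
    summary_median: np.ndarray
    percentile_5: np.ndarray
    percentile_95: np.ndarray
    comparator: str                    # "mean" (adults) or "median" (twins)

    def __post_init__(self):
        if not (np.all(self.percentile_5 <= self.summary_median + 1e-12)
                and np.all(self.summary_median <= self.percentile_95 + 1e-12)):
            raise AssertionError("pointwise percentile ordering violated")

    @property
    def n_subjects(self) -> int:
        return self.per_subject.shape[0]

    @property
    def comparator_curve(self) -> np.ndarray:
        return self.summary_mean if self.comparator == "mean" else self.summary_median

    def comparator_profile(self, subject_id: str,
                           age: float | None = None) -> ConcentrationTimeProfile:
        return ConcentrationTimeProfile(
            subject_id=subject_id, times=self.times,
            concentrations=np.clip(self.comparator_curve, 0.0, None), age=age)


def _summaries(times, curves, comparator) -> PopulationResult:
    curves = np.asarray(curves)
    return PopulationResult(
        times=times,
        per_subject=curves,
        summary_mean=curves.mean(axis=0),
        summary_median=np.median(curves, axis=0),
        percentile_5=np.percentile(curves, 5, axis=0),
        percentile_95=np.percentile(curves, 95, axis=0),
        comparator=comparator,
    )


def _individual_curve(demo: physiology.Demographics, drug, absorption_settings,
                      cl_mult: float, get: float | None, sitt: float | None,
                      doses: Sequence[DoseEvent], t_end: float,
                      output_step: float) -> tuple[np.ndarray, np.ndarray]:
    profile = physiology.scale_profile_to_age(demo)
    kpset = distribution.compute_kp_set(drug, profile)
    cl_model = ontogeny.ClearanceModel(adult_cl_per_kg=drug.cl_per_kg,
                                       fraction_renal=drug.fraction_renal)
    cl = ontogeny.scale_clearance(cl_model, demo, profile) * cl_mult
    ab = None
    if any(d.route == "oral" for d in doses):
        ab = absorption_settings.with_transit(get, sitt)
    model = build_model(profile, kpset, drug, cl, ab)
    res = simulate(model, doses, t_end, output_step=output_step)
    return res.times, res.plasma_concentration


@dataclass(frozen=True)
class AdultStudyArm:
    """Descriptor of one mean-profile adult dataset (dose, route, cohort mix)."""

    dose_mg: float
    route: str                   # "iv" | "oral"
    n_subjects: int = 6
    age_range: tuple[float, float] = (18.0, 45.0)
    female_fraction: float = 0.0
    duration_h: float = 24.0

    def __post_init__(self):
        if self.route not in ("iv", "oral"):
            raise ValueError("route must be 'iv' or 'oral'")
        if self.dose_mg <= 0 or self.n_subjects < 1:
            raise ValueError("dose_mg must be > 0 and n_subjects >= 1")


def simulate_adult_population(arm: AdultStudyArm, n: int = 100,
                              spec: VariabilitySpec | None = None,
                              drug=None,
                              absorption_settings: AbsorptionSettings | None = None,
                              seed: int | np.random.Generator | None = None,
                              output_step: float = 0.1,
                              resample_anthropometrics: bool = True
                              ) -> PopulationResult:
    """Population of n virtual adults matching the arm's demographics/dosing.

    The MEAN plasma curve is the comparator for adult mean observed data.
    """
    spec = spec or VariabilitySpec()
    if drug is None:
        drug = distribution.sotalol_parameters()
    absorption_settings = absorption_settings or AbsorptionSettings()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cl_mult, get, sitt = sample_variability(n, spec, rng)
    ages = rng.uniform(*arm.age_range, n)
    if resample_anthropometrics:
        sexes = np.where(rng.uniform(size=n) < arm.female_fraction,
                         "female", "male")
    else:
        # deterministic mix so populations of different size share the same
        # sex proportions (exact closed-loop identity)
        n_female = round(arm.female_fraction * n)
        sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))
    doses = [DoseEvent(arm.route, arm.dose_mg)]
    curves = []
    subs = rng.spawn(n)  # per-subject substreams, order-independent
    for i in range(n):
        if resample_anthropometrics:
            demo = physiology.sample_demographics(float(ages[i]), str(sexes[i]), subs[i])
        else:
            demo = physiology.Demographics(
                age=float(ages[i]), sex=str(sexes[i]),
                body_weight=physiology.growth_median_weight(float(ages[i]), str(sexes[i])),
                height=170.0)
        times, conc = _individual_curve(
            demo, drug, absorption_settings, float(cl_mult[i]),
            float(get[i]), float(sitt[i]), doses, arm.duration_h, output_step)
        curves.append(conc)
    return _summaries(times, curves, comparator="mean")


@dataclass(frozen=True)
class ChildRecord:
    """One pediatric patient: identity, demographics and dosing."""

    subject_id: str
    age: float                    # years
    sex: str
    body_weight: float            # kg
    height: float                 # cm
    dose_mg_per_kg_day: float
    postmenstrual_age: float | None = None

    @property
    def demographics(self) -> physiology.Demographics:
        return physiology.Demographics(
            age=self.age, sex=self.sex, body_weight=self.body_weight,
            height=self.height, postmenstrual_age=self.postmenstrual_age)

    @property
    def daily_dose_mg(self) -> float:
        return self.dose_mg_per_kg_day * self.body_weight


def steady_state_oral_curve(demo: physiology.Demographics, daily_dose_mg: float,
                            drug, absorption_settings: AbsorptionSettings,
                            cl_mult: float = 1.0, get: float | None = None,
                            sitt: float | None = None,
                            output_step: float = 0.05
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Last-interval (q12h, day 5) steady-state profile for one individual.

    Exploits dose linearity and time invariance: one single-dose simulation
    over the full span is superposed at the 12-h dosing offsets.
    """
    tau = 24.0 / PEDIATRIC_DOSES_PER_DAY
    n_doses = PEDIATRIC_DOSES_PER_DAY * PEDIATRIC_STEADY_STATE_DAYS
    per_dose = daily_dose_mg / PEDIATRIC_DOSES_PER_DAY
    t_end = tau * n_doses
    step_per_tau = int(round(tau / output_step))
    times, conc = _individual_curve(
        demo, drug, absorption_settings, cl_mult, get, sitt,
        [DoseEvent("oral", per_dose)], t_end, output_step)
    n_tau = step_per_tau + 1
    acc = np.zeros(n_tau)
    for k in range(n_doses):
        start = k * step_per_tau
        acc += conc[start:start + n_tau]
    return times[:n_tau], acc


def simulate_virtual_twins(child: ChildRecord, n: int = 100,
                           spec: VariabilitySpec | None = None,
                           drug=None,
                           absorption_settings: AbsorptionSettings | None = None,
                           seed: int | np.random.Generator | None = None,
                           output_step: float = 0.05,
                           resample_anthropometrics: bool = True
                           ) -> PopulationResult:
    """n virtual twins sharing the child's age, sex and dosing.

    Weight and height are resampled from the growth reference (the twins'
    biology varies; the real child's identity does not); the MEDIAN curve is
    the comparator for the child's individual observed profile — the
    contract difference from adult populations.
    """
    spec = spec or VariabilitySpec()
    if drug is None:
        drug = distribution.sotalol_parameters()
    absorption_settings = absorption_settings or AbsorptionSettings()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cl_mult, get, sitt = sample_variability(n, spec, rng, pediatric=child.age < 18)
    curves = []
    subs = rng.spawn(n)  # per-subject substreams, order-independent
    for i in range(n):
        if resample_anthropometrics:
            demo = physiology.sample_demographics(child.age, child.sex, subs[i])
            demo = replace(demo, postmenstrual_age=child.demographics.postmenstrual_age)
        else:
            demo = child.demographics
        times, conc = steady_state_oral_curve(
            demo, child.daily_dose_mg, drug, absorption_settings,
            float(cl_mult[i]), float(get[i]), float(sitt[i]), output_step)
        curves.append(conc)
    return _summaries(times, curves, comparator="median")
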