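"""Synthetic stand-in datasets for the undeposited clinical data.

The real study compared model predictions against plasma profiles from 80
children (six age groups, oral sotalol 1.0-9.9 mg/kg/day, ages 11 days to
17.7 years, 54 boys / 26 girls, 13 premature infants) and 27 adult
mean-profile literature datasets (IV 20-210 mg, oral 40-320 mg).  Neither
collection is public, so this module generates structurally matched
synthetic versions: each child's "observed" profile is a PBPK simulation
under hidden true parameters (per-subject clearance/transit perturbations)
with proportional residual noise; each adult dataset is the noisy mean of a
small simulated cohort.

The hidden truth record makes the generator a test instrument: with the
truth perturbations set to identity and the noise switched off, the whole
evaluation pipeline must return Obs/Pred ratios of exactly one.

Residual noise is mean-one lognormal, exp(sigma Z - sigma^2/2) with
sigma^2 = ln(1 + cv^2), so that observed concentrations are conditionally
unbiased around the model curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import physiology, popsim
from .absorption import AbsorptionSettings
from .distribution import sotalol_parameters
from .nca import ConcentrationTimeProfile
from .popsim import AdultStudyArm, ChildRecord, VariabilitySpec

_DAY = 1.0 / 365.25

#: study age-group bounds (years) used for sampling children
GROUP_AGE_BOUNDS = {
    "neonates": (11 * _DAY, 28 * _DAY),
    "infants": (29 * _DAY, 11.99 / 12.0),
    "toddlers": (1.0, 1.99),
    "preschool": (2.0, 5.99),
    "school": (6.0, 11.99),
    "adolescents": (12.0, 17.7),
}
DEFAULT_GROUP_SIZES = {
    "neonates": 14, "infants": 33, "toddlers": 6,
    "preschool": 10, "school": 13, "adolescents": 4,
}

#: children: 0-12 h, 8 samples; neonates optionally capped below 10 h to
#: exercise the ke-eligibility rule
CHILD_SCHEDULE = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0)
NEONATE_SHORT_SCHEDULE = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
ADULT_SCHEDULE = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Structure of the synthetic pediatric cohort."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    dose_range: tuple[float, float] = (1.0, 9.9)   # mg/kg/day
    sex_split: float = 54.0 / 80.0                  # fraction boys
    residual_error_cv: float = 0.20
    n_premature: int = 13
    neonate_short_fraction: float = 1.0   # fraction of neonates sampled < 10 h
    truth_perturbation: VariabilitySpec = field(default_factory=VariabilitySpec)

    def __post_init__(self):
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.dose_range[0] <= 0 or self.dose_range[0] >= self.dose_range[1]:
            raise ValueError("dose_range must be positive and ordered")
        if self.residual_error_cv < 0:
            raise ValueError("residual_error_cv must be >= 0")

    @property
    def cohort_size(self) -> int:
        return sum(self.group_sizes.values())


def identity_truth_spec() -> VariabilitySpec:
    """Truth perturbations switched off (closed-loop configuration)."""
    return popsim.fixed_variability()


def proportional_noise(conc: np.ndarray, cv: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Mean-one lognormal proportional residual error."""
    if cv == 0:
        return conc
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    eps = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=conc.shape))
    return conc * eps


def generate_pediatric_cohort(spec: SyntheticCohortSpec | None = None,
                              seed: int | np.random.Generator | None = None
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample the cohort table and the hidden truth record.

    Returns ``(cohort, truth)``: one row per child with demographics and
    dosing, and the per-subject true CL multiplier / GET / SITT used when
    the "observed" profiles are simulated.  The truth never appears in the
    cohort table.
    """
    spec = spec or SyntheticCohortSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    k = 0
    for group, n in spec.group_sizes.items():
        lo, hi = GROUP_AGE_BOUNDS[group]
        for _ in range(n):
            k += 1
            age = float(rng.uniform(lo, hi))
            sex = "male" if rng.uniform() < spec.sex_split else "female"
            demo = physiology.sample_demographics(age, sex, rng)
            rows.append({
                "subject_id": f"child_{k:03d}", "age_group": group,
                "age_years": age, "sex": sex,
                "weight_kg": demo.body_weight, "height_cm": demo.height,
                "dose_mg_per_kg_day": float(rng.uniform(*spec.dose_range)),
                "gestational_weeks": 40.0,
            })
    cohort = pd.DataFrame(rows)

    # premature infants live in the two youngest groups; their shorter
    # gestation lowers postmenstrual age and hence renal maturation
    young = cohort.index[cohort["age_group"].isin(["neonates", "infants"])]
    n_prem = min(spec.n_premature, len(young))
    prem_idx = rng.choice(young, size=n_prem, replace=False)
    cohort.loc[prem_idx, "gestational_weeks"] = rng.uniform(28.0, 36.9, n_prem)
    cohort["pma_weeks"] = cohort["gestational_weeks"] + \
        cohort["age_years"] * 52.1775

    cl_mult, get, sitt = popsim.sample_variability(
        len(cohort), spec.truth_perturbation, rng, pediatric=True)
    truth = pd.DataFrame({
        "subject_id": cohort["subject_id"],
        "cl_mult": cl_mult, "get_h": get, "sitt_h": sitt,
    })
    return cohort, truth


def child_record(row: pd.Series) -> ChildRecord:
    return ChildRecord(
        subject_id=row["subject_id"], age=row["age_years"], sex=row["sex"],
        body_weight=row["weight_kg"], height=row["height_cm"],
        dose_mg_per_kg_day=row["dose_mg_per_kg_day"],
        postmenstrual_age=row["pma_weeks"],
    )


def generate_observed_profiles(cohort: pd.DataFrame, truth: pd.DataFrame,
                               drug=None,
                               absorption_settings: AbsorptionSettings | None = None,
                               spec: SyntheticCohortSpec | None = None,
                               seed: int | np.random.Generator | None = None
                               ) -> list[ConcentrationTimeProfile]:
    """Simulate each child's steady-state profile under their true parameters.

    The schedule is 0-12 h (8 points); a configurable fraction of neonates
    is observed only to 8 h, which renders them ke-ineligible downstream.
    """
    spec = spec or SyntheticCohortSpec()
    if drug is None:
        drug = sotalol_parameters()
    if absorption_settings is None or absorption_settings.effective_permeability is None:
        raise ValueError("calibrated absorption settings are required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth_by_id = truth.set_index("subject_id")
    profiles = []
    for _, row in cohort.iterrows():
        rec = child_record(row)
        tr = truth_by_id.loc[rec.subject_id]
        schedule = np.asarray(CHILD_SCHEDULE)
        if row["age_group"] == "neonates" and \
                rng.uniform() < spec.neonate_short_fraction:
            schedule = np.asarray(NEONATE_SHORT_SCHEDULE)
        get = None if math.isnan(tr["get_h"]) else float(tr["get_h"])
        sitt = None if math.isnan(tr["sitt_h"]) else float(tr["sitt_h"])
        times, conc = popsim.steady_state_oral_curve(
            rec.demographics, rec.daily_dose_mg, drug, absorption_settings,
            cl_mult=float(tr["cl_mult"]), get=get, sitt=sitt)
        obs = np.interp(schedule, times, conc)
        obs = proportional_noise(obs, spec.residual_error_cv, rng)
        profiles.append(ConcentrationTimeProfile(
            subject_id=rec.subject_id, times=schedule, concentrations=obs,
            age=rec.age))
    return profiles


# -------------------------------------------------- adult literature stand-in

def default_adult_descriptor() -> pd.DataFrame:
    """Structure of the 27 adult mean-profile datasets (dose, route, mix)."""
    rows = [
        # route, dose_mg, n_datasets, n_subjects, female_fraction, age_lo, age_hi
        ("iv", 20, 1, 6, 0.50, 24, 53), ("iv", 35, 2, 6, 0.50, 18, 38),
        ("iv", 70, 1, 5, 0.00, 22, 43), ("iv", 75, 1, 6, 0.60, 19, 45),
        ("iv", 105, 4, 6, 0.18, 18, 43), ("iv", 140, 2, 5, 0.00, 21, 32),
        ("iv", 210, 2, 6, 0.50, 18, 38),
        ("oral", 40, 1, 5, 0.00, 22, 45), ("oral", 50, 1, 5, 0.00, 22, 43),
        ("oral", 80, 2, 6, 0.60, 19, 45), ("oral", 100, 2, 5, 0.00, 22, 43),
        ("oral", 160, 5, 6, 0.16, 22, 56), ("oral", 200, 1, 5, 0.00, 22, 43),
        ("oral", 300, 1, 5, 0.00, 22, 43), ("oral", 320, 1, 6, 0.10, 28, 56),
    ]
    return pd.DataFrame(rows, columns=[
        "route", "dose_mg", "n_datasets", "n_subjects", "female_fraction",
        "age_lo", "age_hi"])


def generate_adult_datasets(descriptor: pd.DataFrame | None = None,
                            drug=None,
                            absorption_settings: AbsorptionSettings | None = None,
                            spec: VariabilitySpec | None = None,
                            residual_error_cv: float = 0.20,
                            seed: int | np.random.Generator | None = None,
                            resample_anthropometrics: bool = True
                            ) -> list[tuple[AdultStudyArm, ConcentrationTimeProfile]]:
    """Noisy mean "observed" profile for every adult dataset row.

    Each dataset is the mean of its small simulated cohort (5-6 subjects)
    with residual noise scaled by 1/sqrt(n_subjects), mirroring mean-profile
    literature data.
    """
    descriptor = descriptor if descriptor is not None else default_adult_descriptor()
    if drug is None:
        drug = sotalol_parameters()
    spec = spec or VariabilitySpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    k = 0
    for _, row in descriptor.iterrows():
        for _ in range(int(row["n_datasets"])):
            k += 1
            arm = AdultStudyArm(
                dose_mg=float(row["dose_mg"]), route=row["route"],
                n_subjects=int(row["n_subjects"]),
                age_range=(float(row["age_lo"]), float(row["age_hi"])),
                female_fraction=float(row["female_fraction"]))
            if arm.route == "oral" and (
                    absorption_settings is None
                    or absorption_settings.effective_permeability is None):
                raise ValueError("calibrated absorption settings are required "
                                 "for oral datasets")
            pop = popsim.simulate_adult_population(
                arm, n=arm.n_subjects, spec=spec, drug=drug,
                absorption_settings=absorption_settings, seed=rng,
                resample_anthropometrics=resample_anthropometrics)
            sched = np.asarray(ADULT_SCHEDULE)
            mean_obs = np.interp(sched, pop.times, pop.summary_mean)
            cv_mean = residual_error_cv / math.sqrt(arm.n_subjects)
            mean_obs = proportional_noise(mean_obs, cv_mean, rng)
            out.append((arm, ConcentrationTimeProfile(
                subject_id=f"adult_ds_{k:02d}", times=sched,
                concentrations=mean_obs, age=None)))
    return out


# -------------------------------------------------------------------- I/O

def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)
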