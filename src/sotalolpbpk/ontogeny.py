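"""Pediatric clearance scaling via renal maturation and organ physiology.

Sotalol is eliminated entirely by the kidney, so the adult clearance input is
scaled to children by combining

* a sigmoid (Hill) maturation function of postmenstrual age describing
  glomerular-filtration ontogeny (defaults gamma = 3.4, TM50 = 47.7 weeks,
  a published GFR maturation parameterization),
* the individual's kidney blood flow relative to the 70-kg reference adult
  (taken from the physiology tables rather than a fixed allometric
  exponent), and
* the unbound-fraction ratio (a no-op for sotalol, fu = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physiology import ADULT_REFERENCE_AGE, postmenstrual_age_weeks

#: adult reference postmenstrual age (18 years, term birth), weeks
ADULT_PMA_WEEKS = postmenstrual_age_weeks(ADULT_REFERENCE_AGE)


@dataclass(frozen=True)
class ClearanceModel:
    """Adult clearance input and renal-maturation constants."""

    adult_cl_per_kg: float = 0.1125   # L/h/kg, fully renal for sotalol
    fraction_renal: float = 1.0
    maturation_halflife_pma: float = 47.7   # TM50, weeks postmenstrual
    maturation_hill: float = 3.4            # gamma

    def __post_init__(self):
        if self.adult_cl_per_kg <= 0:
            raise ValueError("adult_cl_per_kg must be > 0")
        if not 0 <= self.fraction_renal <= 1:
            raise ValueError("fraction_renal must be in [0, 1]")
        if self.maturation_halflife_pma <= 22:
            raise ValueError("TM50 must exceed 22 weeks")
        if self.maturation_hill <= 0:
            raise ValueError("Hill coefficient must be > 0")


DEFAULT_CLEARANCE_MODEL = ClearanceModel()


def maturation_fraction(postmenstrual_age: float,
                        model: ClearanceModel = DEFAULT_CLEARANCE_MODEL) -> float:
    """Hill maturation function of postmenstrual age (weeks).

    Returns pma^g / (TM50^g + pma^g) in (0, 1); exactly 0.5 at pma = TM50.
    """
    pma = np.asarray(postmenstrual_age, dtype=float)
    if np.any(pma < 22):
        raise ValueError("postmenstrual age must be >= 22 weeks")
    g = model.maturation_hill
    t = model.maturation_halflife_pma
    frac = 1.0 / (1.0 + (t / pma) ** g)
    return float(frac) if frac.ndim == 0 else frac


def gfr_fraction_of_adult(postmenstrual_age: float,
                          model: ClearanceModel = DEFAULT_CLEARANCE_MODEL) -> float:
    """Maturation multiplier normalized to 1 at the 18-year adult reference."""
    ratio = maturation_fraction(postmenstrual_age, model) / maturation_fraction(
        ADULT_PMA_WEEKS, model
    )
    return min(ratio, 1.2)


def scale_clearance(model: ClearanceModel, demographics, profile,
                    fu_ratio: float = 1.0) -> float:
    """Individual total clearance (L/h) scaled from the adult input.

    CL = CL_adult(70 kg) x maturation(pma)/maturation(adult pma)
         x Q_kidney(individual)/Q_kidney(reference adult, 70 kg)
         x fu_child/fu_adult.

    At adult demographics (18 y, 70 kg) this reproduces the input clearance
    exactly; kidney blood flow carries both the body-size and the
    organ-perfusion dependence.
    """
    from .physiology import reference_adult_profile

    if fu_ratio <= 0:
        raise ValueError("fu_ratio must be > 0")
    cl_adult = model.adult_cl_per_kg * 70.0
    mat = maturation_fraction(demographics.postmenstrual_age, model) / \
        maturation_fraction(ADULT_PMA_WEEKS, model)
    mat = min(mat, 1.0)
    ref = reference_adult_profile(demographics.sex, 70.0)
    kidney_factor = profile.organ_blood_flows["kidney"] / \
        ref.organ_blood_flows["kidney"]
    return cl_adult * mat * kidney_factor * fu_ratio


def clearance_per_kg_curve(ages_years, sex: str = "male",
                           model: ClearanceModel = DEFAULT_CLEARANCE_MODEL):
    """Per-kg clearance (L/h/kg) at the growth-reference median weight.

    Convenience export for plotting the composed ontogeny curve.
    """
    from .physiology import Demographics, growth_median_weight, scale_profile_to_age

    out = []
    for age in np.atleast_1d(np.asarray(ages_years, dtype=float)):
        bw = growth_median_weight(age, sex)
        demo = Demographics(age=float(age), sex=sex, body_weight=bw, height=100.0)
        prof = scale_profile_to_age(demo)
        out.append(scale_clearance(model, demo, prof) / bw)
    return np.asarray(out)
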