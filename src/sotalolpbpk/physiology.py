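"""Age- and sex-dependent whole-body physiology.

Organ volumes, blood flows, cardiac output, hematocrit and tissue composition
are built from versioned reference tables shipped with the package
(ICRP-89-style adult reference values with pediatric age curves; tissue
composition from the Rodgers-Rowland publications).  Profiles are constructed
so that two closures hold exactly:

* venous return: the sum of systemic organ blood flows equals cardiac output
  (the lumped "rest" compartment takes the balancing flow), and
* volume: organ volumes plus blood volume reconcile with body weight
  (density ~1 kg/L; "rest" takes the balancing volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

#: organs with their own perfused compartment (blood handled separately)
ORGANS = (
    "adipose", "bone", "brain", "gut", "heart", "kidney", "liver", "lung",
    "muscle", "skin", "spleen", "pancreas", "rest",
)
#: organs drained by the portal vein into the liver
PORTAL_ORGANS = ("gut", "spleen", "pancreas")

_WEEKS_PER_YEAR = 52.1775
_TERM_GESTATION_WEEKS = 40.0
ADULT_REFERENCE_AGE = 18.0


def _load(name: str) -> pd.DataFrame:
    with resources.files("sotalolpbpk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


_ADULT_REF = _load("adult_reference.csv")
_ADULT_SCALARS = _load("adult_scalars.csv").set_index("sex")
_PED_FRAC = _load("pediatric_fractions.csv")
_PED_SCALARS = _load("pediatric_scalars.csv")
_GROWTH = _load("growth_reference.csv")
_TISSUE_COMP = _load("tissue_composition.csv").set_index("organ")


def postmenstrual_age_weeks(age_years: float, gestational_weeks: float = _TERM_GESTATION_WEEKS) -> float:
    """Postmenstrual age (gestational + postnatal) in weeks."""
    return gestational_weeks + age_years * _WEEKS_PER_YEAR


@dataclass(frozen=True)
class Demographics:
    """One individual's covariates.

    ``age`` is in fractional years (an 11-day-old neonate has age
    11/365.25), ``postmenstrual_age`` in weeks and defaults to term birth
    (gestational 40 weeks + postnatal age).
    """

    age: float
    sex: str
    body_weight: float
    height: float
    postmenstrual_age: float | None = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.body_weight <= 0 or self.height <= 0:
            raise ValueError("body_weight and height must be > 0")
        if self.postmenstrual_age is None:
            object.__setattr__(
                self, "postmenstrual_age", postmenstrual_age_weeks(self.age)
            )
        if self.postmenstrual_age < 22:
            raise ValueError("postmenstrual_age must be >= 22 weeks")


@dataclass(frozen=True)
class TissueComposition:
    f_water_extracellular: float
    f_water_intracellular: float
    f_neutral_lipid: float
    f_neutral_phospholipid: float
    conc_acidic_phospholipid: float  # mg per g tissue
    intracellular_pH: float = 7.0
    plasma_pH: float = 7.4

    def __post_init__(self):
        fracs = (self.f_water_extracellular, self.f_water_intracellular,
                 self.f_neutral_lipid, self.f_neutral_phospholipid)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("tissue fractions must lie in [0, 1] and sum to <= 1")
        for ph in (self.intracellular_pH, self.plasma_pH):
            if not 6.5 <= ph <= 7.8:
                raise ValueError("pH out of physiological range [6.5, 7.8]")


@dataclass
class PhysiologyProfile:
    """Complete whole-body physiology of one individual."""

    demographics: Demographics
    organ_volumes: Mapping[str, float]          # L, keys = ORGANS
    blood_volume: float                          # L (whole blood)
    organ_blood_flows: Mapping[str, float]       # L/h supply flows; lung = CO
    cardiac_output: float                        # L/h
    hematocrit: float
    gfr_fraction_adult: float
    tissue_composition: Mapping[str, TissueComposition] = field(repr=False, default=None)

    def __post_init__(self):
        if self.tissue_composition is None:
            self.tissue_composition = default_tissue_composition()
        missing = set(ORGANS) - set(self.organ_volumes)
        if missing:
            raise ValueError(f"missing organ volumes: {sorted(missing)}")
        if any(v <= 0 for v in self.organ_volumes.values()) or self.blood_volume <= 0:
            raise ValueError("all volumes must be > 0")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must be in (0, 1)")
        if not 0 < self.gfr_fraction_adult <= 1.2:
            raise ValueError("gfr_fraction_adult must be in (0, 1.2]")
        total = sum(self.organ_volumes.values()) + self.blood_volume
        bw = self.demographics.body_weight
        if abs(total - bw) > 0.10 * bw:
            raise ValueError(
                f"volume closure violated: organs+blood = {total:.2f} L vs "
                f"body weight {bw:.2f} kg"
            )
        systemic = sum(q for o, q in self.organ_blood_flows.items() if o != "lung")
        if abs(systemic - self.cardiac_output) > 1e-9 * self.cardiac_output:
            raise ValueError("venous-return closure violated")

    @property
    def plasma_volume(self) -> float:
        return self.blood_volume * (1.0 - self.hematocrit)

    @property
    def red_cell_volume(self) -> float:
        return self.blood_volume * self.hematocrit

    @property
    def liver_outflow(self) -> float:
        """Total hepatic venous outflow = hepatic artery + portal inflows."""
        q = self.organ_blood_flows
        return q["liver"] + sum(q[o] for o in PORTAL_ORGANS)

    def to_frame(self) -> pd.DataFrame:
        """Profile as a tidy table (for audit export)."""
        rows = [{"organ": o, "volume_l": self.organ_volumes[o],
                 "flow_l_h": self.organ_blood_flows[o]} for o in ORGANS]
        return pd.DataFrame(rows)


_DEFAULT_COMPOSITION: dict[str, TissueComposition] | None = None


def default_tissue_composition() -> dict[str, TissueComposition]:
    global _DEFAULT_COMPOSITION
    if _DEFAULT_COMPOSITION is None:
        out = {}
        for organ, row in _TISSUE_COMP.iterrows():
            out[organ] = TissueComposition(
                f_water_extracellular=row["f_water_extracellular"],
                f_water_intracellular=row["f_water_intracellular"],
                f_neutral_lipid=row["f_neutral_lipid"],
                f_neutral_phospholipid=row["f_neutral_phospholipid"],
                conc_acidic_phospholipid=row["conc_acidic_phospholipid_mg_g"],
                intracellular_pH=row["intracellular_ph"],
            )
        _DEFAULT_COMPOSITION = out
    return _DEFAULT_COMPOSITION


def _assemble(demographics: Demographics, vol_frac: dict[str, float],
              flow_frac: dict[str, float], blood_frac: float,
              co_per_kg: float, hematocrit: float,
              gfr_fraction: float) -> PhysiologyProfile:
    bw = demographics.body_weight
    volumes = {o: vol_frac[o] * bw for o in vol_frac}
    blood = blood_frac * bw
    # rest closes the volume balance (clamped to stay positive)
    rest_v = bw - sum(volumes.values()) - blood
    volumes["rest"] = max(rest_v, 0.005 * bw)
    co = co_per_kg * bw
    flows = {o: flow_frac[o] * co for o in flow_frac if o != "lung"}
    flows["rest"] = co - sum(flows.values())  # venous-return closure, exact
    if flows["rest"] <= 0:
        raise ValueError("flow fractions exceed cardiac output")
    flows["lung"] = co
    return PhysiologyProfile(
        demographics=demographics,
        organ_volumes=volumes,
        blood_volume=blood,
        organ_blood_flows=flows,
        cardiac_output=co,
        hematocrit=hematocrit,
        gfr_fraction_adult=gfr_fraction,
    )


def reference_adult_profile(sex: str, body_weight: float = 70.0) -> PhysiologyProfile:
    """Reference adult physiology, linearly rescaled to ``body_weight``.

    The embedded reference is a 70-kg male / 60-kg female; organ volumes and
    blood flows scale proportionally with body weight within [40, 150] kg.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not 40.0 <= body_weight <= 150.0:
        raise ValueError(
            f"adult body weight {body_weight} kg outside supported range [40, 150]"
        )
    sc = _ADULT_SCALARS.loc[sex]
    ref = _ADULT_REF[_ADULT_REF["sex"] == sex].set_index("organ")
    vol_frac = ref["volume_frac"].to_dict()
    flow_frac = ref["flow_frac"].to_dict()
    demo = Demographics(
        age=30.0, sex=sex, body_weight=body_weight,
        height=176.0 if sex == "male" else 163.0,
    )
    return _assemble(
        demo, vol_frac, flow_frac,
        blood_frac=sc["blood_l"] / sc["body_weight_kg"],
        co_per_kg=sc["cardiac_output_l_h"] / sc["body_weight_kg"],
        hematocrit=sc["hematocrit"],
        gfr_fraction=1.0,
    )


def _build_ped_interp():
    """Precompute (ages, values) arrays per sex/organ for fast interpolation."""
    tables: dict[str, dict] = {}
    for sex in ("male", "female"):
        sub = _PED_FRAC[_PED_FRAC["sex"] == sex]
        vols, flows = {}, {}
        for organ, grp in sub.groupby("organ"):
            # an organ may tabulate volumes and flows on different age grids
            v = grp.dropna(subset=["volume_frac"]).sort_values("age_y")
            f = grp.dropna(subset=["flow_frac"]).sort_values("age_y")
            vols[organ] = (v["age_y"].to_numpy(), v["volume_frac"].to_numpy())
            flows[organ] = (f["age_y"].to_numpy(), f["flow_frac"].to_numpy())
        sc = _PED_SCALARS[_PED_SCALARS["sex"] == sex].sort_values("age_y")
        tables[sex] = {
            "vols": vols, "flows": flows,
            "ages_sc": sc["age_y"].to_numpy(),
            "co": sc["co_per_kg_l_h"].to_numpy(),
            "hct": sc["hematocrit"].to_numpy(),
            "blood": sc["blood_frac"].to_numpy(),
        }
    return tables


_PED_INTERP = _build_ped_interp()


def _interp_ped(sex: str, age: float):
    t = _PED_INTERP[sex]
    vol_frac = {o: float(np.interp(age, a, v)) for o, (a, v) in t["vols"].items()}
    flow_frac = {o: float(np.interp(age, a, f)) for o, (a, f) in t["flows"].items()}
    co_per_kg = float(np.interp(age, t["ages_sc"], t["co"]))
    hct = float(np.interp(age, t["ages_sc"], t["hct"]))
    blood_frac = float(np.interp(age, t["ages_sc"], t["blood"]))
    return vol_frac, flow_frac, co_per_kg, hct, blood_frac


def scale_profile_to_age(demographics: Demographics) -> PhysiologyProfile:
    """Whole-body physiology for an individual of any age.

    Ages above 18 route through :func:`reference_adult_profile`; pediatric
    ages interpolate the embedded age tables and rescale to the individual's
    body weight.  ``gfr_fraction_adult`` is the renal maturation multiplier
    (postmenstrual-age sigmoid, normalized to 1 at the adult reference age).
    """
    from . import ontogeny  # local import to avoid a cycle

    age = demographics.age
    if age < 0:
        raise ValueError("age must be >= 0")
    gfr = ontogeny.gfr_fraction_of_adult(demographics.postmenstrual_age)
    if age >= ADULT_REFERENCE_AGE:
        prof = reference_adult_profile(demographics.sex, demographics.body_weight)
        return PhysiologyProfile(
            demographics=demographics,
            organ_volumes=prof.organ_volumes,
            blood_volume=prof.blood_volume,
            organ_blood_flows=prof.organ_blood_flows,
            cardiac_output=prof.cardiac_output,
            hematocrit=prof.hematocrit,
            gfr_fraction_adult=gfr,
        )
    vol_frac, flow_frac, co_per_kg, hct, blood_frac = _interp_ped(
        demographics.sex, age
    )
    return _assemble(demographics, vol_frac, flow_frac, blood_frac,
                     co_per_kg, hct, gfr)


def sample_demographics(age: float, sex: str,
                        seed: int | np.random.Generator | None = None) -> Demographics:
    """Draw weight and height for one individual of the given age and sex.

    Both are lognormal around the interpolated growth-reference median; the
    geometric SD places the 3rd/97th percentiles at the tabulated envelope.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = _GROWTH[_GROWTH["sex"] == sex].sort_values("age_y")
    a = min(age, g["age_y"].max())
    wt_med = float(np.interp(a, g["age_y"], g["weight_median_kg"]))
    wt_gsd = float(np.interp(a, g["age_y"], g["weight_gsd"]))
    ht_med = float(np.interp(a, g["age_y"], g["height_median_cm"]))
    ht_gsd = float(np.interp(a, g["age_y"], g["height_gsd"]))
    wt = wt_med * math.exp(rng.normal(0.0, math.log(wt_gsd)))
    ht = ht_med * math.exp(rng.normal(0.0, math.log(ht_gsd)))
    return Demographics(age=age, sex=sex, body_weight=wt, height=ht)


def growth_median_weight(age: float, sex: str) -> float:
    """Median body weight (kg) at the given age from the growth reference."""
    g = _GROWTH[_GROWTH["sex"] == sex].sort_values("age_y")
    return float(np.interp(min(age, g["age_y"].max()), g["age_y"], g["weight_median_kg"]))
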