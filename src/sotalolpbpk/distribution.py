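"""Tissue-to-plasma partition coefficients via the Rodgers-Rowland model.

Sotalol is an ampholyte (acidic pKa 8.28, basic pKa 9.72) whose basic group
dominates at physiological pH, so it is handled under the moderate-to-strong
base branch: partitioning into tissue water follows pH-driven ion trapping,
and binding of the cationic species to tissue acidic phospholipids is
quantified by an association constant (KaAP) back-calculated from the
measured blood-to-plasma concentration ratio.  Full diprotic speciation is
retained in the ionization terms.

For parameter sets whose B/P ratio falls below what water partitioning alone
predicts for red cells, the back-calculated KaAP would be negative; it is
clamped to zero (no acidic-phospholipid affinity) with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd

from .physiology import ORGANS, PhysiologyProfile

PLASMA_PH = 7.4
RED_CELL_PH = 7.2
#: red blood cell composition (intracellular water, neutral lipid,
#: neutral phospholipid fractions; acidic phospholipid mg/g)
RBC_F_IW = 0.63
RBC_F_NL = 0.0017
RBC_F_NP = 0.0029
RBC_AP = 0.5


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical, binding and clearance inputs for one model variant."""

    molecular_weight: float
    logP: float
    pKa_acid: float | None
    pKa_base: float | None
    fu_plasma: float
    blood_plasma_ratio: float
    cl_per_kg: float                 # L/h/kg total IV clearance
    fraction_renal: float
    permeability: float | None = None  # effective intestinal permeability, cm/s
    variant_label: str = "variant_a"

    def __post_init__(self):
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")
        if self.blood_plasma_ratio <= 0:
            raise ValueError("blood_plasma_ratio must be > 0")
        if self.cl_per_kg <= 0:
            raise ValueError("cl_per_kg must be > 0")
        if not 0 <= self.fraction_renal <= 1:
            raise ValueError("fraction_renal must be in [0, 1]")

    def with_permeability(self, p_eff: float) -> "DrugParameters":
        return replace(self, permeability=p_eff)


def sotalol_parameters(variant: str = "variant_a") -> DrugParameters:
    """Sotalol input parameter set.

    ``variant_a`` uses B/P 1.02, ``variant_b`` B/P 0.86 — the two values the
    source models adopted during IV fitting.  The effective permeability is
    left unset; it is produced by the bioavailability calibration.
    """
    bp = {"variant_a": 1.02, "variant_b": 0.86}
    if variant not in bp:
        raise ValueError(f"unknown variant {variant!r}")
    return DrugParameters(
        molecular_weight=272.36,
        logP=0.37,
        pKa_acid=8.28,
        pKa_base=9.72,
        fu_plasma=1.0,
        blood_plasma_ratio=bp[variant],
        cl_per_kg=0.1125,
        fraction_renal=1.0,
        variant_label=variant,
    )


def ionized_fractions(pH: float, pKa_acid: float | None = None,
                      pKa_base: float | None = None):
    """Henderson-Hasselbalch speciation (neutral, cation, anion, zwitterion).

    Acidic and basic groups are treated as independent sites; the zwitterion
    arm is the joint ionization of both and is zero unless both pKas are
    given.  Fractions are >= 0 and sum to 1.
    """
    if not 0 <= pH <= 14:
        raise ValueError("pH must be in [0, 14]")
    cation = 10.0 ** (pKa_base - pH) if pKa_base is not None else 0.0
    anion = 10.0 ** (pH - pKa_acid) if pKa_acid is not None else 0.0
    zwitter = cation * anion
    denom = 1.0 + cation + anion + zwitter
    return (1.0 / denom, cation / denom, anion / denom, zwitter / denom)


def _ionization_ratios(pH: float, pKa_acid, pKa_base):
    """Cationic and anionic concentration ratios relative to the neutral form."""
    cation = 10.0 ** (pKa_base - pH) if pKa_base is not None else 0.0
    anion = 10.0 ** (pH - pKa_acid) if pKa_acid is not None else 0.0
    return cation, anion


def blood_cell_partition(blood_plasma_ratio: float, hematocrit: float,
                         fu_plasma: float = 1.0) -> float:
    """Red-cell-to-plasma partition from the hematocrit identity.

    Kp_BC = (B/P - (1 - Hct)) / Hct; the precondition B/P > 1 - Hct keeps it
    positive.  (Division by fu_plasma gives the unbound-referenced KpuBC used
    in the KaAP back-calculation.)
    """
    if not 0 < hematocrit < 1:
        raise ValueError("hematocrit must be in (0, 1)")
    if blood_plasma_ratio <= (1.0 - hematocrit):
        raise ValueError(
            "blood_plasma_ratio must exceed 1 - hematocrit, otherwise the "
            "hematocrit identity Kp_BC = (B/P - (1 - Hct))/Hct is non-positive"
        )
    return (blood_plasma_ratio - (1.0 - hematocrit)) / hematocrit


@dataclass(frozen=True)
class KpSet:
    """Tissue:plasma partition coefficients plus blood-cell partitioning."""

    kp: Mapping[str, float]
    kp_blood_cells: float
    acidic_phospholipid_affinity: float   # KaAP, back-calculated

    def __post_init__(self):
        if any(v <= 0 for v in self.kp.values()):
            raise ValueError("all Kp must be > 0")
        if self.kp_blood_cells <= 0:
            raise ValueError("kp_blood_cells must be > 0")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"organ": o, "kp": v} for o, v in sorted(self.kp.items())]
        rows.append({"organ": "blood_cells", "kp": self.kp_blood_cells})
        return pd.DataFrame(rows)


def back_calculate_kaap(drug: DrugParameters, hematocrit: float,
                        red_cell_pH: float = RED_CELL_PH) -> float:
    """Acidic-phospholipid association constant from blood-cell partitioning.

    Solves the moderate-to-strong-base red-cell equation for KaAP given the
    measured B/P ratio.  Clamped at zero (with a warning) when the measured
    partitioning is below the water/ionization prediction.
    """
    kpu_bc = blood_cell_partition(drug.blood_plasma_ratio, hematocrit,
                                  drug.fu_plasma) / drug.fu_plasma
    cat_p, an_p = _ionization_ratios(PLASMA_PH, drug.pKa_acid, drug.pKa_base)
    cat_bc, an_bc = _ionization_ratios(red_cell_pH, drug.pKa_acid, drug.pKa_base)
    ion_p = 1.0 + cat_p + an_p
    ion_bc = 1.0 + cat_bc + an_bc
    p = 10.0 ** drug.logP
    lipid = (p * RBC_F_NL + (0.3 * p + 0.7) * RBC_F_NP) / ion_p
    water = RBC_F_IW * ion_bc / ion_p
    residual = kpu_bc - water - lipid
    if cat_bc == 0:
        # no basic group, no cationic species to bind acidic phospholipids
        return 0.0
    if residual < 0:
        warnings.warn(
            f"measured B/P {drug.blood_plasma_ratio} is below the red-cell "
            "water/ionization prediction; acidic-phospholipid affinity "
            "clamped to zero",
            stacklevel=2,
        )
        return 0.0
    return residual * ion_p / (RBC_AP * cat_bc)


def compute_kp_set(drug: DrugParameters, profile: PhysiologyProfile) -> KpSet:
    """Rodgers-Rowland Kp for every perfused tissue (deterministic).

    Kpu_t = f_EW + f_IW (1 + ion_IW)/(1 + ion_p)
            + KaAP [AP]_t cation_IW/(1 + ion_p)
            + (P f_NL + (0.3 P + 0.7) f_NP)/(1 + ion_p)

    and Kp = Kpu x fu_plasma.  Kp is an intensive property: it depends on
    tissue composition only, not on body size.
    """
    kaap = back_calculate_kaap(drug, profile.hematocrit)
    cat_p, an_p = _ionization_ratios(PLASMA_PH, drug.pKa_acid, drug.pKa_base)
    ion_p = 1.0 + cat_p + an_p
    p = 10.0 ** drug.logP
    kp = {}
    for organ in ORGANS:
        tc = profile.tissue_composition.get(organ)
        if tc is None:
            raise ValueError(f"no tissue composition data for organ {organ!r}")
        cat_iw, an_iw = _ionization_ratios(tc.intracellular_pH,
                                           drug.pKa_acid, drug.pKa_base)
        ion_iw = 1.0 + cat_iw + an_iw
        kpu = (
            tc.f_water_extracellular
            + tc.f_water_intracellular * ion_iw / ion_p
            + kaap * tc.conc_acidic_phospholipid * cat_iw / ion_p
            + (p * tc.f_neutral_lipid
               + (0.3 * p + 0.7) * tc.f_neutral_phospholipid) / ion_p
        )
        kp[organ] = kpu * drug.fu_plasma
    kp_bc = blood_cell_partition(drug.blood_plasma_ratio, profile.hematocrit,
                                 drug.fu_plasma)
    return KpSet(kp=kp, kp_blood_cells=kp_bc, acidic_phospholipid_affinity=kaap)


def compute_vss(kpset: KpSet, profile: PhysiologyProfile) -> float:
    """Steady-state volume of distribution, L per kg body weight.

    Vss = (V_plasma + sum_t Kp_t V_t + Kp_BC V_redcells) / body weight.
    """
    total = profile.plasma_volume
    total += sum(kpset.kp[o] * profile.organ_volumes[o] for o in ORGANS)
    total += kpset.kp_blood_cells * profile.red_cell_volume
    return total / profile.demographics.body_weight
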