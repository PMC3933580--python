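"""Generate the embedded physiology data CSVs (run once; output frozen into src/sotalolpbpk/data)."""
import numpy as np
import pandas as pd
import os

OUT = os.path.join(os.path.dirname(__file__), "..", "src", "sotalolpbpk", "data")
os.makedirs(OUT, exist_ok=True)

AGES = [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 18.0]

# ---- adult reference (ICRP-89-style, male 70 kg / female 60 kg) ----
# organ volumes in L for the reference body weight (density ~1 kg/L)
ADULT_VOL_M = {  # 70 kg male
    "adipose": 16.2, "bone": 10.0, "brain": 1.45, "gut": 1.15, "heart": 0.33,
    "kidney": 0.31, "liver": 1.80, "lung": 0.53, "muscle": 28.2, "skin": 3.30,
    "spleen": 0.15, "pancreas": 0.14,
}
ADULT_VOL_F = {  # 60 kg female
    "adipose": 19.0, "bone": 7.60, "brain": 1.30, "gut": 1.00, "heart": 0.25,
    "kidney": 0.28, "liver": 1.40, "lung": 0.42, "muscle": 17.5, "skin": 2.30,
    "spleen": 0.13, "pancreas": 0.12,
}
ADULT_BW = {"male": 70.0, "female": 60.0}
ADULT_BLOOD = {"male": 5.30, "female": 4.10}     # L
ADULT_CO = {"male": 390.0, "female": 354.0}      # L/h
ADULT_HCT = {"male": 0.45, "female": 0.40}

# systemic blood-flow fractions of cardiac output (supply side; liver entry = hepatic artery)
ADULT_FLOW_FRAC = {
    "adipose": 0.05, "bone": 0.05, "brain": 0.12, "gut": 0.15, "heart": 0.04,
    "kidney": 0.19, "liver": 0.065, "muscle": 0.17, "skin": 0.05,
    "spleen": 0.03, "pancreas": 0.01,
    "lung": 1.0,  # pulmonary flow = full cardiac output (in series)
}  # rest closes to 1.0

rows = []
for sex, vols in (("male", ADULT_VOL_M), ("female", ADULT_VOL_F)):
    bw = ADULT_BW[sex]
    for organ, v in vols.items():
        rows.append({"sex": sex, "organ": organ,
                     "volume_frac": v / bw, "flow_frac": ADULT_FLOW_FRAC[organ]})
pd.DataFrame(rows).to_csv(os.path.join(OUT, "adult_reference.csv"), index=False)

pd.DataFrame([
    {"sex": "male", "body_weight_kg": 70.0, "blood_l": 5.30, "cardiac_output_l_h": 390.0, "hematocrit": 0.45},
    {"sex": "female", "body_weight_kg": 60.0, "blood_l": 4.10, "cardiac_output_l_h": 354.0, "hematocrit": 0.40},
]).to_csv(os.path.join(OUT, "adult_scalars.csv"), index=False)

# ---- pediatric age tables: organ volume fraction of body weight ----
# columns at AGES; 18-y column equals the adult fraction (per sex) so the adult
# limit is continuous.  Values follow ICRP-89-style pediatric organ growth.
PED_VOL = {  # age 0, 0.5, 1, 2, 5, 10, 15 (18y filled per sex)
    "adipose": [0.150, 0.230, 0.230, 0.200, 0.150, 0.150, 0.180],
    "bone":    [0.080, 0.085, 0.090, 0.100, 0.110, 0.120, 0.135],
    "brain":   [0.109, 0.088, 0.095, 0.081, 0.066, 0.042, 0.025],
    "gut":     [0.0120, 0.0130, 0.0135, 0.0140, 0.0145, 0.0150, 0.0158],
    "heart":   [0.0057, 0.0055, 0.0050, 0.0048, 0.0045, 0.0044, 0.0044],
    "liver":   [0.0371, 0.0400, 0.0330, 0.0300, 0.0290, 0.0270, 0.0245],
    "lung":    [0.0171, 0.0145, 0.0130, 0.0110, 0.0095, 0.0085, 0.0078],
    "muscle":  [0.220, 0.220, 0.230, 0.260, 0.310, 0.350, 0.400],
    "skin":    [0.0500, 0.0480, 0.0450, 0.0430, 0.0420, 0.0440, 0.0460],
    "spleen":  [0.00286, 0.00270, 0.00260, 0.00250, 0.00240, 0.00230, 0.00220],
    "pancreas":[0.00171, 0.00180, 0.00185, 0.00190, 0.00195, 0.00198, 0.00200],
}
PED_VOL_KIDNEY = [0.0071, 0.0068, 0.0065, 0.0060, 0.0055, 0.0050, 0.0046]
# pediatric flow fractions of CO (supply side); 18-y column = adult values.
PED_FLOW = {
    "adipose": [0.030, 0.033, 0.035, 0.038, 0.042, 0.046, 0.049],
    "bone":    [0.030, 0.033, 0.035, 0.038, 0.042, 0.046, 0.049],
    "brain":   [0.150, 0.250, 0.270, 0.260, 0.230, 0.180, 0.130],
    "gut":     [0.140, 0.142, 0.144, 0.146, 0.148, 0.149, 0.150],
    "heart":   [0.030, 0.032, 0.033, 0.035, 0.037, 0.039, 0.040],
    "liver":   [0.060, 0.061, 0.062, 0.062, 0.063, 0.064, 0.065],
    "muscle":  [0.080, 0.085, 0.090, 0.100, 0.120, 0.145, 0.165],
    "skin":    [0.060, 0.058, 0.056, 0.054, 0.052, 0.051, 0.050],
    "spleen":  [0.030, 0.030, 0.030, 0.030, 0.030, 0.030, 0.030],
    "pancreas":[0.010, 0.010, 0.010, 0.010, 0.010, 0.010, 0.010],
    "lung":    [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
}
# ---- fine age grid for cardiac output and kidney perfusion ----
# Kidney blood flow per kg is designed to be monotone non-decreasing with age
# (maturation of renal clearance is carried separately by the postmenstrual
# sigmoid); fine nodes keep piecewise-linear interpolation of the
# fraction x CO product monotone as well.
FINE_AGES = [0.0, 0.25, 0.5, 1.0, 1.5] + list(np.arange(2.0, 18.5, 1.0))
CO_FINE = [12.9, 11.6, 10.8, 10.0, 9.3, 8.6, 8.1, 7.7, 7.4, 7.15, 6.95, 6.8,
           6.65, 6.5, 6.38, 6.26, 6.14, 6.02, 5.9, 5.79, 5.68]  # + 18y per sex
# target kidney blood flow per kg (L/h/kg), male scale; 18-y value matches the
# adult reference exactly per sex
KID_PERKG = [0.84, 0.90, 0.94, 0.99, 1.02] + \
    [1.040 + (ADULT_CO["male"] / ADULT_BW["male"] * 0.19 - 1.040) * (a - 2.0) / 16.0
     for a in np.arange(2.0, 18.0, 1.0)]

# coarse scalars
PED_HCT =       [0.50, 0.365, 0.37, 0.375, 0.385, 0.40, 0.42]
PED_BLOOD_FRAC = [0.080, 0.078, 0.077, 0.0765, 0.0762, 0.0760, 0.0758]

rows = []
for sex in ("male", "female"):
    bw = ADULT_BW[sex]
    vols = ADULT_VOL_M if sex == "male" else ADULT_VOL_F
    for organ in PED_VOL:
        vfr = PED_VOL[organ] + [vols[organ] / bw]
        ffr = PED_FLOW[organ] + [ADULT_FLOW_FRAC[organ]]
        for a, v, f in zip(AGES, vfr, ffr):
            rows.append({"sex": sex, "organ": organ, "age_y": a,
                         "volume_frac": v, "flow_frac": f})
    # kidney volume on coarse nodes, flow on fine nodes
    kid_v = PED_VOL_KIDNEY + [vols["kidney"] / bw]
    for a, v in zip(AGES, kid_v):
        rows.append({"sex": sex, "organ": "kidney", "age_y": a,
                     "volume_frac": v, "flow_frac": np.nan})
    co18 = ADULT_CO[sex] / ADULT_BW[sex]
    q18 = co18 * ADULT_FLOW_FRAC["kidney"]
    scale = co18 / (ADULT_CO["male"] / ADULT_BW["male"])
    co_fine = [c * scale for c in CO_FINE] + [co18]
    q_fine = [q * scale for q in KID_PERKG] + [q18]
    for a, c, q in zip(FINE_AGES, co_fine, q_fine):
        rows.append({"sex": sex, "organ": "kidney", "age_y": a,
                     "volume_frac": np.nan, "flow_frac": q / c})
pd.DataFrame(rows).to_csv(os.path.join(OUT, "pediatric_fractions.csv"), index=False)

rows = []
for sex in ("male", "female"):
    co18 = ADULT_CO[sex] / ADULT_BW[sex]
    hct18 = ADULT_HCT[sex]
    bl18 = ADULT_BLOOD[sex] / ADULT_BW[sex]
    co_fine = [c * co18 / (ADULT_CO["male"] / ADULT_BW["male"]) for c in CO_FINE] + [co18]
    hct = np.interp(FINE_AGES, AGES, PED_HCT + [hct18])
    blf = np.interp(FINE_AGES, AGES, PED_BLOOD_FRAC + [bl18])
    for a, c, h, b in zip(FINE_AGES, co_fine, hct, blf):
        rows.append({"sex": sex, "age_y": a, "co_per_kg_l_h": c,
                     "hematocrit": h, "blood_frac": b})
pd.DataFrame(rows).to_csv(os.path.join(OUT, "pediatric_scalars.csv"), index=False)

# ---- growth reference (median weight/height by age and sex, lognormal spread) ----
# medians follow WHO/CDC-style growth curves; gsd places the 3rd/97th percentiles
# at roughly median/x1.27 for weight and /x1.08 for height.
G_AGES = [0.0, 0.02, 0.083, 0.25, 0.5, 1, 2, 3, 5, 7, 10, 12, 14, 16, 18]
WT_M = [3.3, 3.6, 4.5, 6.4, 7.9, 9.6, 12.2, 14.3, 18.3, 22.9, 31.2, 39.8, 50.8, 60.8, 68.0]
WT_F = [3.2, 3.4, 4.2, 5.8, 7.3, 8.9, 11.5, 13.9, 18.0, 22.4, 31.9, 41.5, 49.4, 53.5, 57.0]
HT_M = [49.9, 51.1, 54.7, 61.4, 67.6, 75.7, 87.1, 96.1, 109.2, 121.7, 138.6, 149.1, 163.2, 173.4, 176.1]
HT_F = [49.1, 50.3, 53.7, 59.8, 65.7, 74.0, 85.7, 95.1, 108.4, 121.1, 138.4, 151.2, 160.4, 162.5, 163.0]
rows = []
for sex, wt, ht in (("male", WT_M, HT_M), ("female", WT_F, HT_F)):
    for a, w, h in zip(G_AGES, wt, ht):
        rows.append({"sex": sex, "age_y": a, "weight_median_kg": w, "weight_gsd": 1.135,
                     "height_median_cm": h, "height_gsd": 1.042})
pd.DataFrame(rows).to_csv(os.path.join(OUT, "growth_reference.csv"), index=False)

# ---- Rodgers-Rowland tissue composition ----
# fractional extracellular/intracellular water, neutral lipid, neutral
# phospholipid, acidic phospholipid concentration (mg/g), intracellular pH.
TC = {  # organ: (f_ew, f_iw, f_nl, f_np, ap_mg_g)
    "adipose": (0.135, 0.017, 0.845, 0.0016, 0.40),
    "bone":    (0.100, 0.346, 0.017, 0.0017, 0.67),
    "brain":   (0.162, 0.620, 0.0391, 0.0015, 0.40),
    "gut":     (0.282, 0.475, 0.0487, 0.0163, 2.41),
    "heart":   (0.320, 0.456, 0.0115, 0.0166, 2.25),
    "kidney":  (0.273, 0.483, 0.0207, 0.0162, 5.03),
    "liver":   (0.161, 0.573, 0.0348, 0.0252, 4.56),
    "lung":    (0.336, 0.446, 0.0219, 0.0148, 3.91),
    "muscle":  (0.118, 0.630, 0.0238, 0.0072, 1.53),
    "skin":    (0.382, 0.291, 0.0284, 0.0111, 1.32),
    "spleen":  (0.207, 0.579, 0.0201, 0.0198, 3.18),
    "pancreas":(0.120, 0.664, 0.0403, 0.0090, 1.67),
    # "rest" is a muscle-like lumped carcass compartment
    "rest":    (0.150, 0.550, 0.040, 0.0080, 1.50),
}
rows = [{"organ": o, "f_water_extracellular": v[0], "f_water_intracellular": v[1],
         "f_neutral_lipid": v[2], "f_neutral_phospholipid": v[3],
         "conc_acidic_phospholipid_mg_g": v[4], "intracellular_ph": 7.0}
        for o, v in TC.items()]
pd.DataFrame(rows).to_csv(os.path.join(OUT, "tissue_composition.csv"), index=False)

print("wrote tables to", OUT)
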