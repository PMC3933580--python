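# Methods

## Model overview

Sotalol is a hydrophilic, fully renally cleared, non-metabolized beta
blocker (fu = 1, BCS class I).  These properties make it close to a
best-case drug for whole-body PBPK: disposition is governed by anatomy,
perfusion and glomerular filtration, with no enzymatic ontogeny, no plasma
protein binding, and no dissolution limitation.  The package implements a
perfusion-limited (flow-limited) whole-body model: thirteen tissue
compartments (adipose, bone, brain, gut, heart, kidney, liver, lung,
muscle, skin, spleen, pancreas, and a lumped "rest"), arterial and venous
blood pools, and — for oral dosing — a stomach plus a seven-segment
small-intestinal transit chain.  Gut, spleen and pancreas drain through the
portal vein into the liver; the lung sits in series with cardiac output.
State variables are amounts (mg); the observable is venous plasma
concentration, converted from whole blood through the blood-to-plasma
ratio B/P.

Renal elimination is assigned to the kidney compartment as a *plasma*
clearance acting on the arterial plasma concentration entering the kidney.
This choice is deliberate: it makes Dose/AUC of the sampled (venous) plasma
recover the clearance input exactly, which is both how the clearance was
defined from clinical data and the basis of the closed-loop clearance
check.  Tying elimination to the kidney's local venous concentration
instead would inflate sampled-plasma AUC by a factor 1 + CL/(B/P·Q_kidney)
(~10% for sotalol) and break the identity.

## Integration

The full system (including the absorption chain and auxiliary states) is
linear and time-invariant.  The default propagator therefore advances the
state with the matrix exponential of the constant rate matrix over each
output step (piecewise-constant infusion inputs handled by the augmented-
matrix construction).  This is exact to machine precision, uncondition-
ally stable, and conservative by construction: the mass-balance residual
of any run is ~1e-13 relative.  A conventional stiff solver (LSODA,
rtol 1e-8, atol 1e-10 mg) is retained behind the same interface and is
cross-checked against the exponential path in the tests (agreement better
than 1e-6 relative); it is the escape hatch for any future nonlinear
extension.  Cumulative plasma AUC is carried as an auxiliary ODE state, so
exposure integrals used in calibration and clearance recovery carry no
output-grid discretization error — important because the post-bolus venous
mixing transient (~0.01 h) is far faster than any reasonable output step.

## Physiology tables

The commercial tools' physiology databases are proprietary, so the package
ships its own open tables (`src/sotalolpbpk/data/`): ICRP-89-style
reference adults (70-kg male, 60-kg female), pediatric organ-fraction age
curves, and WHO/CDC-style growth references for weight/height sampling
(lognormal around the median, geometric SDs placing the 3rd/97th
percentiles at the tabulated envelope).  Two closures hold exactly at
every age by construction: organ volumes plus blood reconcile with body
weight (the "rest" compartment takes the balance), and systemic organ
flows sum to cardiac output (the "rest" flow closes venous return).  The
18-year column of every pediatric table equals the adult reference, so the
adult limit is continuous; profiles between tabulated ages are linear
interpolations.

Kidney blood flow is tabulated on a finer age grid than the other organs,
and its values are chosen so that renal perfusion *per kilogram* is
monotone non-decreasing from birth to adulthood.  This is a deliberate
design constraint: per-kg clearance in the model is the product of the
maturation sigmoid and per-kg kidney perfusion, and the package asserts
that this composition never decreases with age.  Piecewise-linear
interpolation of a product of opposing slopes can create small local
humps; the fine grid keeps any such curvature below the growth of the
product between nodes.

Any open compendium differs in detail from the (unpublished) vendor
tables; the resulting systematic differences are accepted and are one
reason the package's outputs should be compared with reported values at
the tens-of-percent level, not digit-by-digit.

## Tissue partitioning

Partition coefficients use the Rodgers–Rowland mechanistic equations for
moderate-to-strong bases.  Sotalol's basic pKa (9.72) dominates at
physiological pH (99.5% cationic in plasma); the acidic group (pKa 8.28)
is retained in the speciation terms.  The two ionizable groups are treated
as independent sites; the joint (zwitterionic) arm is reported by the
speciation function but excluded from the partitioning denominators by
default, since macro-pKa data cannot resolve the microconstants (a config
switch exposes the alternative).

The acidic-phospholipid association constant KaAP is back-calculated from
red-cell partitioning: Kp_BC = (B/P − (1 − Hct))/Hct, then the red-cell
equation is solved for KaAP.  Red-cell constants: intracellular water
fraction 0.63, neutral lipid 0.0017, neutral phospholipid 0.0029, acidic
phospholipid 0.5 mg/g, pH 7.2 (plasma 7.4, intracellular 7.0).  The
back-calculation is numerically delicate: the water/ionization term alone
predicts Kp_BC ≈ 1.00 at Hct 0.45, so KaAP is the small difference between
two similar numbers and is very sensitive to the red-cell water fraction
(published values for human erythrocytes span ~0.60–0.72).  For the
variant-B parameter set (B/P 0.86) the measured partitioning falls *below*
the water prediction and no positive KaAP exists; the package clamps it to
zero with a warning, i.e. variant B carries no acidic-phospholipid term.
This is why the package's variant-A/variant-B Vss gap (1.32 vs 1.14 L/kg)
is wider than the 1.3 vs 1.22 L/kg the two commercial tools reported —
their internal variant handling is not public.

## Absorption and calibration

Drug enters the stomach in solution (no dissolution step — sotalol is
highly soluble), empties first-order at 1/GET (GET 0.5 h), transits seven
intestinal segments at n/SITT each (SITT 4 h), and is absorbed from
segment i at k_a,i = 2·P_eff/r_i (adult radii 1.53 → 1.00 cm duodenum to
ileum; pediatric radii scale as (BW/70)^(1/3); GET/SITT means are kept at
adult values, with the wider pediatric GET range entering only through
population variability).  Because sotalol has no gut or hepatic
extraction, F = fa, and fa has the closed form 1 − Π_i kt/(kt + k_a,i),
which the simulated fraction absorbed matches to ~1e-6.

The effective permeability is *not* taken from in vitro data (measured
apparent permeabilities are known to underpredict sotalol absorption).
Instead it is calibrated: a Brent root-find on the simulated
AUC(oral)/AUC(IV) ratio in the 70-kg reference adult against the 90%
bioavailability target, bracketed by inverting the closed-form fa.  The
calibrated P_eff is 1.20 × 10⁻⁴ cm/s — the magnitude of measured human
jejunal permeabilities for well-absorbed compounds.

## Clearance ontogeny

Adult total clearance (0.1125 L·h⁻¹·kg⁻¹, fully renal; 7.875 L/h for
70 kg) is scaled to an individual as

CL = CL_adult(70 kg) × M(PMA)/M(PMA_adult) × Q_kidney/Q_kidney,ref × fu_ratio

where M is the Hill sigmoid M(PMA) = PMA^γ/(TM50^γ + PMA^γ) with the
published GFR maturation constants TM50 = 47.7 weeks postmenstrual age and
γ = 3.4, Q_kidney is the individual's kidney blood flow (carrying both
body size and perfusion maturation, in place of a fixed allometric
exponent), and fu_ratio = 1 for sotalol.  At 18 years / 70 kg the identity
CL = 7.875 L/h holds exactly.  An 11-day-old term neonate has
M(41.6 wk) ≈ 0.39 and per-kg clearance ≈ 0.035 L·h⁻¹·kg⁻¹ — under a third
of the adult value — and per-kg clearance reaches 95% of adult before age
two.  Premature infants enter only through postmenstrual age (gestation
28–37 weeks at birth), not through separate organ tables.

## Populations, twins and dosing assumptions

Adult virtual populations match each dataset's dose, route, age range and
sex mix; the *mean* curve is the comparator, mirroring mean observed
literature profiles.  Pediatric virtual twins share a child's age, sex and
absolute dose, with weight and height resampled from the growth reference;
the *median* curve is the comparator.  Inter-individual variability:
CL lognormal GSD 1.3; GET uniform 0.2–1.9 h (adults) / 0.2–2.1 h
(children); SITT normal 4 ± 1 h truncated at zero.  The alternative
CV/Weibull set (CL 30% CV, GET 38% CV, SITT Weibull α 2.92 / β 4.04) is a
config toggle.  One master seed drives everything; per-subject substreams
are spawned deterministically, so populations are reproducible and
order-independent.

Pediatric dosing regimens are not reported beyond mg/kg/day.  The package
assumes twice-daily (q12h) dosing simulated to day 5, with the last
dosing interval as the steady-state profile.  q12h (rather than q8h) was
chosen because sotalol is conventionally dosed twice daily in children and
because the 0–12 h sampling schedule — and with it the printed "≥ 10 h"
ke-eligibility rule — can only fit inside a dosing interval of at least
12 h.  Model linearity lets the steady-state curve be built by
superposition of one single-dose simulation, which is what makes
80-child × 100-twin studies tractable.

## Synthetic "observed" data

The clinical comparison data are not public.  The generator reproduces
their structure: 80 children in six age groups (14/33/6/10/13/4), ages 11
days–17.7 years, 54:26 boys:girls, doses uniform in 1.0–9.9 mg/kg/day, 13
premature infants among neonates/infants; and 27 adult mean-profile
datasets (7 IV dose levels 20–210 mg, 8 oral dose levels 40–320 mg, five
to six subjects each).  Each child's "observed" profile is the model's own
prediction under hidden per-subject true parameters (CL/GET/SITT drawn
from the variability spec) with mean-one lognormal proportional noise
(default CV 20%; median |ε − 1| ≈ 13.5%).  Mean-one noise
(exp(σZ − σ²/2)) keeps observed concentrations conditionally unbiased, so
Obs/Pred ratios are centered at 1 by construction.  Children are sampled
0–12 h (8 points); neonates are observed only to 8 h by default, which
exercises the pediatric ke-exclusion rule (14/80 ineligible, mirroring the
reported 66/80 eligible).

What passing closed-loop tests do and do not show: with noise off,
identity truth, variability off and resampling off, the pipeline returns
ratios of exactly 1 in all seven strata — this validates the plumbing
(simulation, NCA, matching, statistics) but cannot validate the model
against reality, because the synthetic data are generated by the same
model.  Real observed data would add model misspecification on top of the
residual noise; the headline neonatal underprediction reported for the
commercial tools is therefore *not* reproducible from synthetic data, and
the package does not claim it.

## Evaluation statistics

PE = (C_pred − C_obs)/C_obs × 100% per concentration point (predictions
interpolated onto observed times; observed zeros excluded with a logged
warning), APE = |PE|; MDPE and MDAPE are medians with percentile bootstrap
95% CIs (10,000 replicates, seeded).  Obs/Pred ratios of AUC_last, Cmax,
tmax and ke are summarized per age group as arithmetic means with
percentile bootstrap CIs (geometric mean available), classified against
the twofold range [0.5, 2], and counted against the closed interval
[0.8, 1.25].  tmax ties break to the earliest time; ke is the unweighted
least-squares slope of the last three log concentrations; AUC is never
extrapolated to infinity in the evaluation pathway (extrapolation is used
only inside calibration/clearance recovery where the simulated grid spans
many half-lives).  Age groups: neonates 0–28 d (closed), infants to
< 12 mo, toddlers < 2 y, preschool < 6 y, school < 12 y, adolescents
< 18 y, adults ≥ 18 y.

### Known statistical limitation: small-group bootstrap coverage

Percentile bootstrap CIs of a mean undercover for very small samples: the
interval is built from the resampling distribution, whose spread
underestimates the sampling error by roughly √((n−1)/n) and ignores the
t-correction.  Measured over 200 noise replicates with the study's group
sizes, the 95% CI of the group mean AUC ratio covers the true value ~95%
of the time for n = 14 and n = 33, but only ~85% for n = 6 (toddlers) and
~80% for n = 4 (adolescents).  This is a property of the prescribed
statistic at the study's printed group sizes, not of the implementation;
the corresponding test documents it and the two smallest groups fail its
90% coverage bar.  Consumers of per-group CIs for groups of fewer than ~10
subjects should treat them as optimistic.

## Problem sizes used in the shipped checks

The test suite runs the full pipeline at reduced scale — cohorts of 1–2
children per group, 2–3 twins, 4 adult datasets, and bootstrap replicate
counts of 200–10,000 depending on the assertion — chosen so the entire
suite completes in well under a minute while every structural property
(closures, identities, determinism, eligibility rules) is exercised at
full fidelity.  The statistical coverage check uses the full 80-child
cohort structure with 200 noise replicates and 2,000-replicate bootstrap
CIs.  Default sizes for interactive use remain 100 twins / 100 virtual
adults per population.

## Known limitations

- Open physiology surrogates differ from vendor databases; Vss and
  concentration curves match reported values at the ~10% level, not
  exactly.
- KaAP back-calculation is ill-conditioned for drugs with B/P near or
  below the red-cell water prediction (variant B degenerates to zero
  affinity).
- No dissolution, no colonic absorption (hook present, off), no
  pH-dependent regional permeability (per-segment multiplier hook only),
  no correlated covariates beyond weight/height-for-age, no disease
  states, no ethnicity-specific physiology.
- Preterm physiology enters only via postmenstrual-age clearance
  maturation.
- The IV literature data are simulated as boluses; infusion durations were
  not reported (infusions are supported via `DoseEvent.infusion_duration`).
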