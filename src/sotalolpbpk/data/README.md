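# Embedded reference tables

All files are versioned with the package and are the single source of
physiological truth for the model; they are read only through
`sotalolpbpk.physiology`.

- `adult_reference.csv`, `adult_scalars.csv` — reference adult anatomy
  (organ volumes as fractions of body weight, blood-flow fractions of
  cardiac output, blood volume, hematocrit) in the style of the ICRP
  Publication 89 reference individuals (70-kg male, 60-kg female).
- `pediatric_fractions.csv`, `pediatric_scalars.csv` — pediatric age curves
  of the same quantities, following ICRP-89-style organ growth; the kidney
  blood flow column is tabulated on a finer age grid so that per-kg renal
  perfusion is monotone non-decreasing with age by construction (see
  docs/methods.md).  The 18-year column equals the adult reference values,
  making the adult limit continuous.
- `growth_reference.csv` — median body weight and height by age and sex
  with lognormal spread factors, in the style of WHO/CDC growth references;
  the geometric SDs place the 3rd/97th percentiles at the tabulated curves.
- `tissue_composition.csv` — tissue composition for the Rodgers-Rowland
  partitioning equations (extra/intracellular water, neutral lipid, neutral
  phospholipid fractions, acidic phospholipid concentration, intracellular
  pH), from the published Rodgers-Rowland tissue composition tables; the
  lumped "rest" compartment uses muscle-like averages.

These tables are open surrogates for the proprietary physiology databases
inside commercial PBPK tools; small systematic differences from those tools
are expected and documented in docs/methods.md.
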