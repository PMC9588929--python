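# Zanubrutinib compound file.
# Sources: published in-vitro/physicochemical characterization (see docs/methods.md).
# Solubility is not reported with the other physicochemical properties and is
# an assumed aqueous (intrinsic) value; flagged below.
schema: pbpkddi-drug/1
name: zanubrutinib
molecular_weight: 471.55
ionization:
  - {type: base, pKa: 3.3}
logP: 4.2
solubility_mg_ml: 0.295
solubility_assumed: true
fu_plasma: 0.0582
blood_plasma_ratio: 0.804
permeability:
  peff_human: 0.9          # 10^-4 cm/s
absorption_model: segmented_gi
distribution_model: full
elimination_pathways:
  - route: hepatic_CYP3A4
    kinetics: {linear_clint_hlm: 120.0}     # µL/min/mg microsomal protein
  - route: hepatic_additional
    kinetics: {linear_clint_hlm: 60.0}      # non-CYP3A microsomal clearance
  - route: renal
    kinetics: {systemic_renal: 0.5}         # L/h
distribution:
  kp_method: rodgers_rowland
  # Predicted partition coefficients for this high-logP base overestimate the
  # clinically apparent distribution volume; scalar set during single-dose
  # verification calibration (docs/methods.md).
  kp_scalar: 0.2
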