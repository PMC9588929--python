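# Voriconazole compound file.
# Hepatic elimination is represented by the aggregate microsomal intrinsic
# clearance (it is not split by enzyme); voriconazole therefore acts purely
# as a CYP3A4 inhibitor in interaction simulations.
# fu_gut is not reported and is assumed equal to fu_plasma.
schema: pbpkddi-drug/1
name: voriconazole
molecular_weight: 349.3
ionization:
  - {type: base, pKa: 1.6}
logP: 1.8
solubility_mg_ml: 3.2
fu_plasma: 0.42
fu_gut: 0.42
blood_plasma_ratio: 1.0
permeability:
  peff_human: 3.8          # 10^-4 cm/s
absorption_model: first_order
distribution_model: full
elimination_pathways:
  - route: hepatic_additional
    kinetics: {linear_clint_hlm: 4.3}       # aggregate hepatic CLint
  - route: renal
    kinetics: {systemic_renal: 0.096}       # L/h
interaction:
  target_enzyme: CYP3A4
  ki_um: 0.66
  basis: unbound
distribution:
  kp_method: rodgers_rowland
  # Predicted partition coefficients underestimate voriconazole's extensive
  # tissue distribution (literature Vss ≈ 4.6 L/kg); scalar set during
  # single-dose verification calibration (docs/methods.md).
  kp_scalar: 3.0
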