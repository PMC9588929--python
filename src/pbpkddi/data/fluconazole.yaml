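# Fluconazole compound file.
# The published parameter table reports only the renal clearance (0.86 L/h).
# The non-renal remainder is back-calculated from the observed single-dose
# exposure: CL/F = 100 mg / 93 mg·h/L = 1.075 L/h total; non-renal plasma
# clearance 0.215 L/h; reverse well-stirred scaling (Qh 87 L/h, fu,b 0.89,
# MPPGL 40 mg/g, liver 1650 g) gives the microsomal value below.
# Permeability is Caco-2 Papp, converted by the fixed jejunal calibration line.
schema: pbpkddi-drug/1
name: fluconazole
molecular_weight: 306.3
ionization:
  - {type: base, pKa: 1.76}
logP: 0.2
solubility_mg_ml: 1.39
fu_plasma: 0.89
fu_gut: 0.89
blood_plasma_ratio: 1.0
permeability:
  papp_caco2: 29.8         # 10^-6 cm/s
absorption_model: first_order
distribution_model: minimal
elimination_pathways:
  - route: hepatic_additional
    kinetics: {linear_clint_hlm: 0.0612}    # back-calculated, see header
  - route: renal
    kinetics: {systemic_renal: 0.86}        # L/h
interaction:
  target_enzyme: CYP3A4
  ki_um: 10.7
  basis: unbound
distribution:
  kp_method: rodgers_rowland
  # predicted Kp slightly under-represents fluconazole's total body water
  # distribution; scalar set during single-dose verification calibration
  kp_scalar: 1.4
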