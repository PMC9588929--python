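# Itraconazole compound file.
# CYP3A4 metabolism is saturable (recombinant-enzyme Km/Vmax); the very low
# Km means hepatic elimination saturates at therapeutic concentrations, which
# also captures auto-inhibition.  No renal pathway is reported.
# Absorption is strongly solubility-limited (aqueous solubility 9.64 µg/mL);
# it is represented by the first-order model with a documented constant
# absorbed fraction rather than the segmented dissolution model.
schema: pbpkddi-drug/1
name: itraconazole
molecular_weight: 705.6
ionization:
  - {type: base, pKa: 4.28}
logP: 4.47
solubility_mg_ml: 0.00964
fu_plasma: 0.016
fu_gut: 0.016
blood_plasma_ratio: 0.58
permeability:
  peff_human: 0.28         # 10^-4 cm/s
absorption_model: first_order
absorption:
  fa: 0.65                 # solubility-limited absorbed fraction (capsule)
  # 2*Peff/r under-predicts the observed absorption rate for this compound;
  # ka pinned to the observed single-dose Tmax during verification calibration
  ka_override_per_h: 0.4
distribution_model: minimal
elimination_pathways:
  - route: hepatic_CYP3A4
    kinetics: {km_um: 0.004, vmax_pmol_min_pmol: 0.065}
interaction:
  target_enzyme: CYP3A4
  ki_um: 0.001
  basis: unbound
distribution:
  kp_method: rodgers_rowland
  # slow-tissue (adipose/muscle/bone) pool split off the systemic compartment:
  # itraconazole shows a pronounced distribution phase after the peak
  peripheral_compartment: true
  # see docs/methods.md for the verification calibration of this compound
  kp_scalar: 0.8
metabolism:
  # recombinant-CYP3A4 activity scaled to the in-vivo system; calibrated
  # against the observed single-dose exposure (docs/methods.md)
  rcyp_isef: 0.3
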