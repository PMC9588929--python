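# Acalabrutinib compound file (diprotic base).
# CYP3A4 intrinsic clearance is recombinant-enzyme normalized (µL/min/pmol)
# and scaled through the hepatic CYP3A4 abundance; the additional microsomal
# clearance is a parallel non-CYP3A pathway.
schema: pbpkddi-drug/1
name: acalabrutinib
molecular_weight: 465.5
ionization:
  - {type: base, pKa: 3.54}
  - {type: base, pKa: 5.77}
logP: 2.03
fu_plasma: 0.026
fu_gut: 0.026
blood_plasma_ratio: 0.787
permeability:
  peff_human: 4.0          # 10^-4 cm/s
absorption_model: first_order
distribution_model: minimal
elimination_pathways:
  - route: hepatic_CYP3A4
    kinetics: {linear_clint_rcyp: 9.63}     # µL/min/pmol CYP3A4
  - route: hepatic_additional
    kinetics: {linear_clint_hlm: 289.5}     # µL/min/mg microsomal protein
  - route: renal
    kinetics: {systemic_renal: 1.33}        # L/h
distribution:
  kp_method: rodgers_rowland
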