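# Tissue composition table for partition-coefficient prediction.
# Fractional tissue volumes: extracellular water (f_ew), intracellular water
# (f_iw), neutral lipids (f_nl), neutral phospholipids (f_np); alb_ratio is
# the tissue:plasma albumin concentration ratio used for the extracellular
# protein-binding term.  Values are standard literature composition data for
# human tissues (see docs/methods.md); "rest" is a carcass average.
plasma:
  f_water: 0.945
  f_nl: 0.0035
  f_np: 0.00225
intracellular_ph: 7.0
plasma_ph: 7.4
tissues:
  adipose:  {f_ew: 0.135, f_iw: 0.017, f_nl: 0.853,  f_np: 0.0016, alb_ratio: 0.049}
  bone:     {f_ew: 0.100, f_iw: 0.346, f_nl: 0.017,  f_np: 0.0017, alb_ratio: 0.100}
  brain:    {f_ew: 0.162, f_iw: 0.620, f_nl: 0.039,  f_np: 0.0015, alb_ratio: 0.048}
  gut:      {f_ew: 0.282, f_iw: 0.475, f_nl: 0.038,  f_np: 0.0125, alb_ratio: 0.158}
  heart:    {f_ew: 0.320, f_iw: 0.456, f_nl: 0.014,  f_np: 0.0111, alb_ratio: 0.157}
  kidney:   {f_ew: 0.273, f_iw: 0.483, f_nl: 0.012,  f_np: 0.0240, alb_ratio: 0.130}
  liver:    {f_ew: 0.161, f_iw: 0.573, f_nl: 0.014,  f_np: 0.0240, alb_ratio: 0.086}
  lung:     {f_ew: 0.336, f_iw: 0.446, f_nl: 0.022,  f_np: 0.0128, alb_ratio: 0.212}
  muscle:   {f_ew: 0.118, f_iw: 0.630, f_nl: 0.010,  f_np: 0.0072, alb_ratio: 0.064}
  skin:     {f_ew: 0.382, f_iw: 0.291, f_nl: 0.060,  f_np: 0.0044, alb_ratio: 0.277}
  spleen:   {f_ew: 0.207, f_iw: 0.579, f_nl: 0.0077, f_np: 0.0113, alb_ratio: 0.097}
  rest:     {f_ew: 0.200, f_iw: 0.450, f_nl: 0.050,  f_np: 0.0050, alb_ratio: 0.100}
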