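# Methods

`pbpkddi` is a physiologically-based pharmacokinetic (PBPK) simulator built to
quantify CYP3A4-mediated drug–drug interactions between two BTK inhibitors
(zanubrutinib, acalabrutinib) and three triazole antifungals (voriconazole,
fluconazole, itraconazole). This note documents the model structure, the
system and compound parameters, the calibration procedure, the numerical
choices, and the known limitations — in particular what the passing checks do
and do not demonstrate.

## Model structure

Each compound is assembled from three exchangeable blocks.

**Absorption.** Two descriptions are available:

* *First-order*: the oral dose (scaled by an absorbed fraction `fa`) enters a
  single depot and permeates at `ka = 2·Peff/r` — the cylindrical
  small-intestine approximation with radius r = 1.75 cm. Where only a Caco-2
  permeability is reported (fluconazole), it is converted to a jejunal Peff
  by the fixed correlation `log10 Peff = 0.4926·log10 Papp − 0.1454`.
* *Segmented GI* (zanubrutinib): a dissolution–transit chain of seven
  segments (stomach, duodenum, two jejunal, two ileal, colon) with
  Noyes–Whitney dissolution, pH-dependent solubility for ionizable bases
  (Henderson–Hasselbalch), first-order transit, and permeation of dissolved
  drug at `2·Peff/r` per segment (colon down-weighted ×0.1). Particle radius
  defaults to 10 µm monodisperse. Lag times are zero. The absorbed fraction
  emerges from the competition between permeation and transit. No
  supersaturation, precipitation, bile-micelle solubilization or
  enterohepatic recirculation is modeled.

Absorbed drug crosses the enterocytes, where gut-wall CYP3A4 removes a
fraction `1 − Fg` following the Qgut model:
`Fg = Qgut/(Qgut + fu_gut·CLint_gut/d)` with
`Qgut = Qvilli·CLperm/(Qvilli + CLperm)`, `CLperm = Peff·A`. The divisor `d`
collects competitive terms: co-administered inhibitors contribute
`I_u,ent/Ki`, and a saturable (Michaelis–Menten) substrate contributes its own
`C_u,ent/Km` — without the self-saturation term, itraconazole's gut
extraction would be grossly over-predicted, since its enterocyte
concentrations sit far above its 0.004 µM Km. The enterocyte concentration
driver is the absorption flux divided by the villous blood flow (18 L/h),
unbound by `fu_gut`.

**Distribution.** Tissue:plasma partition coefficients (Kp) are predicted
from a bundled tissue-composition table by either the Rodgers–Rowland
weak-base/neutral equations (default — all five compounds have base pKa ≤
5.8 and are essentially un-ionized at plasma pH) or
Poulin–Theil–Berezhkovskiy. Adipose and bone use the vegetable-oil surrogate
`log Dvo = 1.115·logP − 1.35`. A per-compound `kp_scalar` may rescale the
predicted set (the standard compound-file handle when the prediction
mis-states the clinically apparent volume); all resolved Kp values are
written to the scenario log.

* *Minimal PBPK* (acalabrutinib, fluconazole, itraconazole): one systemic
  compartment plus a mechanistic well-stirred liver receiving the portal
  absorption flux. Optionally the slowly perfused tissues (adipose, muscle,
  bone) are split into a flow-limited peripheral compartment — enabled for
  itraconazole, whose observed single-dose profile shows a pronounced
  distribution phase that a one-compartment systemic pool cannot produce.
* *Full PBPK* (zanubrutinib, voriconazole): perfusion-limited tissue blocks
  `dC_t/dt = Q_t/V_t·(C_art − C_t·Rbp/Kp_t)` for eleven tissues, lung in
  series between the venous and arterial pools, liver receiving hepatic
  artery plus the portal vein draining the gut compartment. Reported plasma
  concentration is venous blood over Rbp.

**Elimination.** In-vitro intrinsic clearances are scaled to the whole liver:
microsomal values by MPPGL × liver weight; recombinant-enzyme values
additionally by the hepatic CYP3A4 abundance and an inter-system
extrapolation factor (ISEF, default 1). Saturable pathways scale Vmax the
same way and leave Km untouched. Hepatic elimination acts on the unbound
liver-compartment concentration (`C_liver·fup/Kp_liver`), which reproduces
the well-stirred model at steady state and, during absorption, exposes the
liver to the elevated portal inlet — the mechanism behind the strong
first-pass interactions seen with acalabrutinib. Renal clearance acts on the
kidney (full model) or systemic (minimal model) plasma concentration.

**Interaction.** Only reversible competitive inhibition is modeled: each
inhibitor's unbound liver concentration divides the CYP3A4-pathway CLint of
every *other* compound by `1 + Σ I_u/Ki` (equivalently multiplies Km), and
its unbound enterocyte concentration does the same for gut-wall CLint
(toggleable with `--no-gut-ddi`). Ki values are unbound-basis constants —
itraconazole's 0.001 µM is only plausible on an unbound basis. A compound
never inhibits itself through its Ki; auto-inhibition of itraconazole is
carried by its saturable Km. No mechanism-based inactivation and no
induction are modeled (no such parameters are reported).

## System parameters

Healthy-adult constants (declared in `default_physiology()`): hepatic blood
flow 87 L/h (portal 65.25 + arterial 21.75), liver 1650 g, MPPGL 40 mg/g,
hepatic CYP3A4 abundance 137 pmol/mg, total small-intestinal CYP3A4 70 nmol,
villous flow 18 L/h, intestinal radius 1.75 cm and surface area 6600 cm²,
cardiac output 390 L/h with reference-man tissue volumes and flows, plasma
volume 3 L. These are standard literature values and were **not** adjusted
during calibration.

## Compound files and calibration

All parameters reported for the five compounds (pKa, MW, logP, solubility,
fup, fu,gut, Rbp, Peff/Papp, CLint, Km/Vmax, CLR, Ki) are taken at face value
in the bundled YAML files. Gaps are closed as follows, with every assumed
value flagged in the file:

* zanubrutinib solubility is not reported; 0.295 mg/mL intrinsic is assumed.
* voriconazole fu,gut is not reported; assumed equal to fup (0.42).
* fluconazole's non-renal clearance is not reported; back-calculated from the
  observed single-dose exposure (CL/F = 100 mg / 93 mg·h/L = 1.075 L/h;
  non-renal 0.215 L/h; reverse well-stirred scaling gives 0.0612 µL/min/mg).
* voriconazole's aggregate hepatic CLint (4.3 µL/min/mg) is not split by
  enzyme, so voriconazole acts purely as an inhibitor in DDI runs.

Remaining free handles were calibrated **once, against the single-dose
verification dataset only** (observed Cmax/Tmax/AUC of the five compounds),
before any DDI scenario was evaluated:

* `kp_scalar`: zanubrutinib 0.2 and itraconazole 0.8 (the Rodgers–Rowland
  prediction overstates Vss for these high-logP bases), voriconazole 3.0 and
  fluconazole 1.4 (prediction understates their tissue distribution;
  literature Vss for voriconazole is ≈ 4.6 L/kg).
* itraconazole: recombinant-CYP3A4 ISEF 0.3 — face-value scaling of the
  reported Km/Vmax yields near flow-limited clearance and a ~50-fold
  under-prediction of exposure; `fa` 0.65 (solubility-limited absorption of
  the capsule, represented as a documented constant rather than through the
  segmented model); `ka` 0.4 h⁻¹ (2·Peff/r from the reported Peff gives a
  20 h Tmax against an observed 4.4 h). The grid of candidate calibrations
  was ranked purely by the verification fit, with one physiological side
  constraint: whole-liver Vmax must admit a steady state under chronic
  200 mg once-daily dosing.

The AUClast verification windows mirror the sampling horizons of the observed
studies (24 h for zanubrutinib, acalabrutinib and itraconazole — the latter's
reference value is an AUC0–24; 12 h for voriconazole, consistent with the
printed AUClast/Cmax ratio; fluconazole uses AUC∞). Voriconazole is verified
at its 300 mg reference dose although the DDI scenarios use 200 mg; the
verification report notes the discrepancy.

## Study designs

Verification: single oral doses of zanubrutinib 80 mg, acalabrutinib 100 mg,
voriconazole 300 mg, fluconazole 100 mg, itraconazole 200 mg; fold error
`max(obs/pred, pred/obs)` on Cmax and AUC must stay below 2.

DDI: paired runs (substrate alone vs co-administered) on identical grids.
Single-dose design: zanubrutinib 160 mg or acalabrutinib 100 mg with one
simultaneous 200 mg inhibitor dose, AUC to the shared 96-h horizon. Multiple
dose: substrate twice daily (zanubrutinib 14 days, acalabrutinib 7 days) with
fluconazole or itraconazole 200 mg once daily, or voriconazole 400 mg twice
daily on day 1 then 200 mg twice daily; summaries are taken over the
substrate's final dosing interval (the source tables do not state their AUC
window; this choice is recorded in the scenario log). First doses of both
compounds are simultaneous at t = 0 ("co-administered" with no stated
offset).

## Numerics

Stiff-capable integration (LSODA) piecewise between dose events, which are
applied as state increments; rtol 1e-6, atol 1e-9 mg. Output grid 0.25 h
with 0.05 h refinement for 3 h after each dose. Halving tolerances moves
Cmax/AUC by < 0.1%; whole-horizon mass balance closes to < 0.5% on linear
scenarios and is written to every scenario log. The log-linear trapezoid uses
the log-down branch only when both concentrations are positive and strictly
decreasing (intervals touching zero fall back to the linear branch);
interval width is Δt = t_{i+1} − t_i. λz is fitted over the last 3–6
positive points after Tmax by best adjusted R². Ties for Cmax report the
earliest time. Concentrations are clipped at zero on output; profiles that
underflow to zero are trimmed before λz fitting.

## Synthetic cohort

The generator draws physiologically plausible first-order/minimal/linear
compounds (uniform within documented ranges; inhibitors always carry a Ki)
and virtual physiologies as lognormal perturbations of the defaults — CV 30%
on the clearance drivers (MPPGL, CYP3A4 abundance) and 20% on flows and
volumes, applied as joint scale factors so the flow-balance invariants hold
by construction; Ki is never varied. One seed fixes all randomness. It
emulates between-subject variability in clearance and physiology only: no
covariate structure (age/sex/weight), no within-subject variability, no
measurement-error model beyond the multiplicative lognormal noise used in the
recovery tests. Passing recovery tests therefore demonstrate numerical
identifiability of the reduced one-compartment parameters under idealized
noise, not fidelity to any real population.

## Known limitations

* **Substrate effects on the inhibitors are absent.** Zanubrutinib reduces
  the exposure of CYP3A substrates (voriconazole, itraconazole), but no
  induction or inactivation parameters are reported, so the triazole
  kinetics here are unaffected by the co-administered BTK inhibitor. The
  model consequently over-predicts the zanubrutinib/itraconazole multiple-dose
  interaction (simulated ≈ +143% AUC vs ≈ +48% reported) and ranks
  itraconazole slightly above voriconazole for zanubrutinib. The printed
  zanubrutinib/itraconazole and acalabrutinib/itraconazole ratios (1.48 vs
  3.64) are mutually inconsistent under pure competitive inhibition with a
  shared inhibitor exposure, so no parameterization of this model class can
  reproduce both.
* Voriconazole's saturable CYP2C19-mediated nonlinearity is flattened into a
  single linear aggregate CLint.
* Kp scalars and the itraconazole ISEF/fa/ka are calibrated constants, not
  predictions; transporters, permeability-limited tissues, food effects, IV
  dosing, and special populations are out of scope.
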