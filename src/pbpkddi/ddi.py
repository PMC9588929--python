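"""CYP3A4 drug-drug interaction study orchestration.

For each substrate/inhibitor pair the study runs two simulations on identical
grids — substrate alone, and substrate co-administered with the inhibitor —
and reports the paired PK summaries, their ratios and percent increases.

Designs mirror the published clinical scenarios:

* ``single`` — one substrate dose (zanubrutinib 160 mg, acalabrutinib 100 mg)
  with one simultaneous 200 mg inhibitor dose; AUC to the shared 96-h horizon.
* ``multiple`` — substrate twice daily (zanubrutinib 160 mg for 14 days,
  acalabrutinib 100 mg for 7 days) with the inhibitor once daily at 200 mg
  (fluconazole, itraconazole) or twice daily at 200 mg after a 400 mg
  twice-daily loading day (voriconazole); summaries over the substrate's
  final dosing interval.

A closed-form static competitive-inhibition oracle
(:func:`static_auc_ratio`) is provided for cross-checking the dynamic engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .engine import Scenario, SolverSettings, simulate, steady_state_metrics
from .params import DrugParameters, Regimen, default_physiology, load_drug_parameters
from .pk_metrics import PKSummary, summarize

Design = Literal["single", "multiple"]

SINGLE_HORIZON_H = 96.0

SUBSTRATE_DESIGNS = {
    "zanubrutinib": {"single_dose_mg": 160.0, "multiple_dose_mg": 160.0,
                     "interval_h": 12.0, "days": 14},
    "acalabrutinib": {"single_dose_mg": 100.0, "multiple_dose_mg": 100.0,
                      "interval_h": 12.0, "days": 7},
}

INHIBITOR_DESIGNS = {
    "voriconazole": {"single_dose_mg": 200.0, "multiple": "bid_loading"},
    "fluconazole": {"single_dose_mg": 200.0, "multiple": "qd"},
    "itraconazole": {"single_dose_mg": 200.0, "multiple": "qd"},
}


def substrate_regimen(name: str, design: Design) -> Regimen:
    spec = SUBSTRATE_DESIGNS[name]
    if design == "single":
        return Regimen.single(name, spec["single_dose_mg"])
    n = int(spec["days"] * 24 / spec["interval_h"])
    return Regimen.repeating(name, spec["multiple_dose_mg"], spec["interval_h"], n)


def inhibitor_regimen(name: str, design: Design, days: int) -> Regimen:
    spec = INHIBITOR_DESIGNS[name]
    if design == "single":
        return Regimen.single(name, spec["single_dose_mg"])
    if spec["multiple"] == "qd":
        return Regimen.repeating(name, 200.0, 24.0, days)
    # voriconazole: 400 mg twice daily on day 1, then 200 mg twice daily
    return Regimen.repeating(
        name, 200.0, 12.0, (days - 1) * 2, loading=[(400.0, 0.0), (400.0, 12.0)]
    )


@dataclass(frozen=True)
class DDIResult:
    substrate: str
    inhibitor: Optional[str]
    design: Design
    alone: PKSummary
    combined: PKSummary
    scenario_logs: dict = field(default_factory=dict, compare=False)

    @property
    def cmax_ratio(self) -> float:
        return self.combined.cmax_ng_ml / self.alone.cmax_ng_ml

    @property
    def tmax_ratio(self) -> float:
        return self.combined.tmax_h / self.alone.tmax_h if self.alone.tmax_h else 1.0

    @property
    def auc_ratio(self) -> float:
        return self.combined.auc_ng_h_ml / self.alone.auc_ng_h_ml

    @property
    def auc_percent_increase(self) -> float:
        return (self.auc_ratio - 1.0) * 100.0

    @property
    def cmax_percent_increase(self) -> float:
        return (self.cmax_ratio - 1.0) * 100.0


def _summaries(
    substrate: DrugParameters,
    sub_reg: Regimen,
    inhibitor: Optional[DrugParameters],
    inh_reg: Optional[Regimen],
    design: Design,
    horizon: float,
    solver: SolverSettings,
    gut_ddi: bool,
) -> tuple[PKSummary, dict]:
    scenario = Scenario(
        substrate=substrate,
        substrate_regimen=sub_reg,
        inhibitor=inhibitor,
        inhibitor_regimen=inh_reg,
        physiology=default_physiology(),
        horizon_h=horizon,
        gut_ddi=gut_ddi,
        solver=solver,
    )
    profile = simulate(scenario)[substrate.name]
    if design == "single":
        return summarize(profile.times_h, profile.conc_ng_ml, "last"), profile.log
    m = steady_state_metrics(profile, sub_reg)
    return (
        PKSummary(
            cmax_ng_ml=m.cmax_ng_ml,
            tmax_h=m.tmax_h,
            auc_ng_h_ml=m.auc_tau_ng_h_ml,
            auc_variant="tau",
        ),
        {**profile.log, "interval_h": list(m.interval),
         "accumulation_index": round(m.accumulation_index, 4)},
    )


def run_ddi_study(
    substrate_name: str,
    inhibitor_name: Optional[str],
    design: Design = "multiple",
    solver: SolverSettings | None = None,
    gut_ddi: bool = True,
) -> DDIResult:
    """Paired alone / with-inhibitor simulation for one substrate.

    ``inhibitor_name`` may be None (or "none"): the combined arm then equals
    the alone arm and all ratios are 1 — useful as a null-perturbation check.
    A substrate without a CYP3A4 pathway is simulated with a warning-level
    note in the log (ratios near 1 are expected), not an error.
    """
    solver = solver or SolverSettings()
    substrate = load_drug_parameters(substrate_name)
    sub_reg = substrate_regimen(substrate_name, design)
    days = SUBSTRATE_DESIGNS[substrate_name]["days"]
    horizon = (
        SINGLE_HORIZON_H if design == "single" else days * 24.0
    )

    inhibitor = None
    inh_reg = None
    if inhibitor_name and inhibitor_name != "none":
        inhibitor = load_drug_parameters(inhibitor_name)
        inh_reg = inhibitor_regimen(inhibitor_name, design, days)

    alone, log_alone = _summaries(
        substrate, sub_reg, None, None, design, horizon, solver, gut_ddi
    )
    if inhibitor is None:
        combined, log_comb = alone, log_alone
    else:
        combined, log_comb = _summaries(
            substrate, sub_reg, inhibitor, inh_reg, design, horizon, solver, gut_ddi
        )
    logs = {"alone": log_alone, "combined": log_comb}
    if not substrate.has_cyp3a4_pathway():
        logs["note"] = "substrate has no CYP3A4 pathway; ratios near 1 expected"
    return DDIResult(
        substrate=substrate_name,
        inhibitor=inhibitor_name if inhibitor is not None else None,
        design=design,
        alone=alone,
        combined=combined,
        scenario_logs=logs,
    )


def static_auc_ratio(fm_cyp3a4: float, fg: float, i_u_um: float, ki_um: float) -> float:
    """Static competitive-inhibition oral AUC ratio:

        AUCR = [1 / (fm/(1 + I_u/Ki) + (1 − fm))] · [Fg' / Fg]

    where Fg' is the gut extraction under inhibition,
    Fg' = Fg / (Fg + (1 − Fg)/(1 + I_u/Ki)).  fm is the CYP3A4 fraction of
    hepatic intrinsic clearance; I_u the unbound inhibitor concentration at
    the enzyme.
    """
    if not 0.0 <= fm_cyp3a4 <= 1.0:
        raise ValueError("fm must lie in [0, 1]")
    if not 0.0 < fg <= 1.0:
        raise ValueError("Fg must lie in (0, 1]")
    factor = 1.0 + i_u_um / ki_um
    hepatic = 1.0 / (fm_cyp3a4 / factor + (1.0 - fm_cyp3a4))
    fg_prime = fg / (fg + (1.0 - fg) / factor)
    return hepatic * fg_prime / fg


def report_tables(results: list[DDIResult]) -> "object":
    """Tabular document mirroring the published DDI table layout: three rows
    (alone / DDI / ratio) per substrate-inhibitor-design block; ratios to two
    decimals.  Returns a pandas DataFrame."""
    import pandas as pd

    if not results:
        raise ValueError("no results to report")
    rows = []
    for r in results:
        inh = r.inhibitor or "none"
        base = {"substrate": r.substrate, "inhibitor": inh, "design": r.design}
        rows.append(
            {**base, "row": f"Alone ({r.design} dose)",
             "cmax_ng_ml": round(r.alone.cmax_ng_ml, 1),
             "tmax_h": round(r.alone.tmax_h, 2),
             "auc_ng_h_ml": round(r.alone.auc_ng_h_ml, 0)}
        )
        rows.append(
            {**base, "row": f"DDI with {inh} ({r.design} dose)",
             "cmax_ng_ml": round(r.combined.cmax_ng_ml, 1),
             "tmax_h": round(r.combined.tmax_h, 2),
             "auc_ng_h_ml": round(r.combined.auc_ng_h_ml, 0)}
        )
        rows.append(
            {**base, "row": f"Ratio with {inh} ({r.design} dose)",
             "cmax_ng_ml": round(r.cmax_ratio, 2),
             "tmax_h": round(r.tmax_ratio, 2),
             "auc_ng_h_ml": round(r.auc_ratio, 2)}
        )
    return pd.DataFrame(rows)
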