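"""Scenario assembly and dynamic simulation.

A :class:`Scenario` pairs a substrate (drug + regimen) with an optional
CYP3A4 inhibitor (drug + regimen, or a concentration clamp for analytic
cross-checks), on shared physiology.  :func:`build_system` assembles one ODE
right-hand side covering both compounds; :func:`simulate` integrates it with
a stiff-capable solver, applying doses as discontinuous state increments, and
returns one plasma concentration-time profile per compound.

Interaction coupling is evaluated at every right-hand-side call: each
inhibitor contributes its unbound liver-compartment concentration to the
hepatic competitive-inhibition factor of the other compound's CYP3A4
pathways, and its unbound enterocyte concentration (absorption flux over
villous blood flow) to the gut-wall factor entering the Qgut model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from . import units
from .absorption import SegmentedGIModel, first_order_ka, gut_extraction_fraction
from .distribution import (
    FullLayout,
    MinimalLayout,
    full_pbpk_layout,
    minimal_pbpk_volumes,
    predict_kp_set,
    vss_from_kp,
)
from .elimination import build_clearance_model, gut_cyp3a4_clint_l_h, gut_cyp3a4_km_um
from .params import DrugParameters, Physiology, Regimen, default_physiology

# arterial / venous blood pool volumes for the full model, L
V_ARTERIAL_L = 1.7
V_VENOUS_L = 3.9


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    method: str = "LSODA"
    max_step: float = math.inf

    def tightened(self, factor: float = 2.0) -> "SolverSettings":
        return SolverSettings(
            rtol=self.rtol / factor,
            atol=self.atol / factor,
            method=self.method,
            max_step=self.max_step,
        )


@dataclass(frozen=True)
class ClampedInhibitor:
    """An inhibitor held at a constant total plasma concentration (mg/L);
    used for closed-form cross-checks of the dynamic interaction coupling."""

    drug: DrugParameters
    conc_plasma_mg_l: float


@dataclass
class Scenario:
    substrate: DrugParameters
    substrate_regimen: Regimen
    inhibitor: Optional[DrugParameters] = None
    inhibitor_regimen: Optional[Regimen] = None
    clamped_inhibitor: Optional[ClampedInhibitor] = None
    physiology: Physiology = field(default_factory=default_physiology)
    horizon_h: float = 96.0
    gut_ddi: bool = True
    grid_base_h: float = 0.25
    grid_fine_h: float = 0.05
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        names = [self.substrate.name]
        if self.inhibitor is not None:
            if self.inhibitor_regimen is None:
                raise ValueError("inhibitor requires a regimen")
            names.append(self.inhibitor.name)
        if len(set(names)) != len(names):
            raise ValueError("overlapping compound names in scenario")
        for reg in self.regimens():
            if reg.last_dose_time_h >= self.horizon_h:
                raise ValueError("simulation horizon does not cover all dose times")

    def regimens(self) -> list[Regimen]:
        regs = [self.substrate_regimen]
        if self.inhibitor_regimen is not None:
            regs.append(self.inhibitor_regimen)
        return regs


@dataclass
class ConcentrationTimeProfile:
    compound: str
    times_h: np.ndarray
    conc_ng_ml: np.ndarray
    log: dict = field(default_factory=dict)

    def window(self, t0: float, t1: float) -> "ConcentrationTimeProfile":
        m = (self.times_h >= t0 - 1e-9) & (self.times_h <= t1 + 1e-9)
        return ConcentrationTimeProfile(
            compound=self.compound,
            times_h=self.times_h[m],
            conc_ng_ml=self.conc_ng_ml[m],
            log=self.log,
        )


class _CompoundRuntime:
    """Resolved constants and state layout for one compound in one system."""

    def __init__(
        self,
        drug: DrugParameters,
        regimen: Regimen,
        physiology: Physiology,
        offset: int,
    ):
        self.drug = drug
        self.regimen = regimen
        self.phys = physiology
        self.cl = build_clearance_model(drug, physiology)
        self.kp_set = predict_kp_set(drug, physiology)

        # --- absorption ---
        self.segmented: Optional[SegmentedGIModel] = None
        if drug.absorption_model == "segmented_gi":
            self.segmented = SegmentedGIModel(drug, physiology)
            n_abs = self.segmented.n_states
        else:
            self.ka = first_order_ka(drug, physiology)
            n_abs = 1
        self.fa = drug.absorption.fa

        # --- gut first pass (Qgut model) ---
        clint_gut = gut_cyp3a4_clint_l_h(drug, physiology)
        clperm = units.permeation_clearance_l_h(
            drug.permeability.peff_cm_s(), physiology.intestinal_surface_area_cm2
        )
        qvilli = physiology.villous_blood_flow_l_h
        self.qgut = qvilli * clperm / (qvilli + clperm)
        self.fugut_clint_gut = drug.fu_gut_effective * clint_gut
        # saturable gut metabolism: the compound's own enterocyte concentration
        # competes at the enzyme exactly like an inhibitor
        self.gut_km_um = gut_cyp3a4_km_um(drug)

        # --- distribution ---
        self.full_layout: Optional[FullLayout] = None
        self.minimal_layout: Optional[MinimalLayout] = None
        if drug.distribution_model == "full":
            self.full_layout = full_pbpk_layout(drug, self.kp_set, physiology)
            lay = self.full_layout
            self.tissues = list(lay.tissues)
            self.t_q = np.array([lay.flows_l_h[t] for t in self.tissues])
            self.t_v = np.array([lay.volumes_l[t] for t in self.tissues])
            self.t_kp = np.array([lay.kp[t] for t in self.tissues])
            self.i_liver = self.tissues.index("liver")
            self.i_gut = self.tissues.index("gut")
            self.i_kidney = self.tissues.index("kidney")
            n_dist = 3 + len(self.tissues)  # ven, lung, art + tissues
            self.kp_liver = lay.kp["liver"]
            self.v_liver = lay.volumes_l["liver"]
        else:
            self.minimal_layout = minimal_pbpk_volumes(drug, self.kp_set, physiology)
            n_dist = 3 if self.minimal_layout.has_peripheral else 2
            self.kp_liver = self.minimal_layout.kp_liver
            self.v_liver = self.minimal_layout.v_liver_l

        # --- state layout ---
        self.abs_slice = slice(offset, offset + n_abs)
        self.dist_slice = slice(offset + n_abs, offset + n_abs + n_dist)
        bk = offset + n_abs + n_dist
        self.i_elim_hep = bk
        self.i_elim_ren = bk + 1
        self.i_elim_gut = bk + 2
        self.i_transit_out = bk + 3
        self.n_states = n_abs + n_dist + 4
        self.offset = offset

        self.mw = drug.molecular_weight
        self.ki_um = drug.interaction.ki_um if drug.interaction else None
        self.unabsorbed_mg = 0.0  # accrued at dose events (first-order fa < 1)

    # -- interaction signals ------------------------------------------------

    def unbound_liver_um(self, y: np.ndarray) -> float:
        if self.full_layout is not None:
            a_liver = y[self.dist_slice][3 + self.i_liver]
        else:
            a_liver = y[self.dist_slice][1]
        cu = max(a_liver, 0.0) / self.v_liver * self.drug.fu_plasma / self.kp_liver
        return units.mg_per_l_to_um(cu, self.mw)

    def absorption_flux_mg_h(self, y: np.ndarray) -> float:
        if self.segmented is not None:
            ya = y[self.abs_slice]
            n = self.segmented.n
            return float(
                np.sum(self.segmented.kperm * np.maximum(ya[n:], 0.0))
            )
        return self.ka * max(y[self.abs_slice][0], 0.0)

    def unbound_enterocyte_um(self, y: np.ndarray) -> float:
        flux = self.absorption_flux_mg_h(y)
        conc = self.drug.fu_gut_effective * flux / self.phys.villous_blood_flow_l_h
        return units.mg_per_l_to_um(conc, self.mw)

    def fg(self, gut_factor: float) -> float:
        if self.fugut_clint_gut <= 0:
            return 1.0
        return self.qgut / (self.qgut + self.fugut_clint_gut / gut_factor)

    # -- derivative ---------------------------------------------------------

    def derivative(
        self,
        y: np.ndarray,
        dy: np.ndarray,
        hepatic_factor: float,
        gut_factor: float,
    ) -> None:
        drug, phys = self.drug, self.phys
        rbp = drug.blood_plasma_ratio

        # absorption
        if self.segmented is not None:
            ya = y[self.abs_slice]
            n = self.segmented.n
            ds, dd, flux, transit_out = self.segmented.derivative(ya[:n], ya[n:])
            dy[self.abs_slice.start : self.abs_slice.start + n] = ds
            dy[self.abs_slice.start + n : self.abs_slice.stop] = dd
            dy[self.i_transit_out] = transit_out
        else:
            a_depot = max(y[self.abs_slice][0], 0.0)
            flux = self.ka * a_depot
            dy[self.abs_slice.start] = -flux

        if self.gut_km_um is not None:
            gut_factor = gut_factor + self.unbound_enterocyte_um(y) / self.gut_km_um
        fg = self.fg(gut_factor)
        to_liver = flux * fg
        dy[self.i_elim_gut] = flux * (1.0 - fg)

        # distribution + elimination
        d0 = self.dist_slice.start
        if self.full_layout is not None:
            yd = y[self.dist_slice]
            a_ven, a_lung, a_art = yd[0], yd[1], yd[2]
            a_t = yd[3:]
            co = self.full_layout.cardiac_output_l_h
            cb_ven = a_ven / V_VENOUS_L
            cb_art = a_art / V_ARTERIAL_L
            cb_lung_out = a_lung / self.full_layout.v_lung_l * rbp / self.full_layout.kp_lung
            cb_t_out = a_t / self.t_v * rbp / self.t_kp

            qha = phys.hepatic_artery_flow_l_h
            qpv = phys.portal_vein_flow_l_h

            # generic perfusion-limited tissues
            dt = self.t_q * (cb_art - cb_t_out)

            # liver: artery + portal (gut outflow) + absorbed flux − outflow − metabolism
            cu_liver = max(a_t[self.i_liver], 0.0) / self.v_liver * drug.fu_plasma / self.kp_liver
            elim_hep = self.cl.hepatic_elimination_rate_mg_h(cu_liver, hepatic_factor)
            dt[self.i_liver] = (
                qha * cb_art
                + qpv * cb_t_out[self.i_gut]
                - (qha + qpv) * cb_t_out[self.i_liver]
                + to_liver
                - elim_hep
            )
            # gut tissue is perfused by the portal flow
            dt[self.i_gut] = qpv * (cb_art - cb_t_out[self.i_gut])

            # renal elimination from the kidney compartment (plasma-referenced)
            c_kid_plasma = max(a_t[self.i_kidney], 0.0) / self.t_v[self.i_kidney] / self.t_kp[self.i_kidney]
            elim_ren = self.cl.renal_l_h * c_kid_plasma
            dt[self.i_kidney] -= elim_ren

            venous_return = float(np.sum(self.t_q * cb_t_out)) - self.t_q[
                self.i_gut
            ] * cb_t_out[self.i_gut] - self.t_q[self.i_liver] * cb_t_out[self.i_liver]
            venous_return += (qha + qpv) * cb_t_out[self.i_liver]

            dy[d0] = venous_return - co * cb_ven            # venous pool
            dy[d0 + 1] = co * (cb_ven - cb_lung_out)        # lung
            dy[d0 + 2] = co * cb_lung_out - float(np.sum(self.t_q * cb_art))  # arterial
            dy[d0 + 3 : self.dist_slice.stop] = dt
        else:
            lay = self.minimal_layout
            yd = y[self.dist_slice]
            a_sys, a_liver = yd[0], yd[1]
            qh = phys.hepatic_blood_flow_l_h
            c_sys = a_sys / lay.v_systemic_l          # plasma
            cb_sys = c_sys * rbp
            cb_liv_out = a_liver / lay.v_liver_l * rbp / self.kp_liver
            cu_liver = max(a_liver, 0.0) / lay.v_liver_l * drug.fu_plasma / self.kp_liver
            elim_hep = self.cl.hepatic_elimination_rate_mg_h(cu_liver, hepatic_factor)
            elim_ren = self.cl.renal_l_h * max(c_sys, 0.0)
            dy[d0] = qh * (cb_liv_out - cb_sys) - elim_ren
            dy[d0 + 1] = qh * cb_sys + to_liver - qh * cb_liv_out - elim_hep
            if lay.has_peripheral:
                # flow-limited exchange with the lumped slow-tissue pool
                c_per = yd[2] / lay.v_peripheral_l
                flux_per = lay.q_peripheral_l_h * (c_sys - c_per)
                dy[d0] -= flux_per
                dy[d0 + 2] = flux_per

        dy[self.i_elim_hep] = elim_hep
        dy[self.i_elim_ren] = elim_ren

    # -- dosing / observation ------------------------------------------------

    def apply_dose(self, y: np.ndarray, dose_mg: float) -> None:
        if self.segmented is not None:
            y[self.abs_slice.start] += dose_mg  # into stomach solid
        else:
            y[self.abs_slice.start] += self.fa * dose_mg
            self.unabsorbed_mg += (1.0 - self.fa) * dose_mg

    def plasma_conc_mg_l(self, y: np.ndarray) -> float:
        if self.full_layout is not None:
            cb_ven = y[self.dist_slice][0] / V_VENOUS_L
            return cb_ven / self.drug.blood_plasma_ratio
        return y[self.dist_slice][0] / self.minimal_layout.v_systemic_l

    def body_amount_mg(self, y: np.ndarray) -> float:
        return float(np.sum(y[self.dist_slice]))


@dataclass
class ODESystem:
    scenario: Scenario
    compounds: list[_CompoundRuntime]
    n_states: int
    dose_events: list[tuple[float, int, float]]  # (time, compound index, mg)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        # interaction signals from every inhibitor-bearing compound
        hep_terms = np.zeros(len(self.compounds))
        gut_terms = np.zeros(len(self.compounds))
        clamp_hep = clamp_gut = 0.0
        clamp = self.scenario.clamped_inhibitor
        if clamp is not None and clamp.drug.interaction is not None:
            i_u = units.mg_per_l_to_um(
                clamp.conc_plasma_mg_l * clamp.drug.fu_plasma, clamp.drug.molecular_weight
            )
            clamp_hep = i_u / clamp.drug.interaction.ki_um
            clamp_gut = clamp_hep
        for j, c in enumerate(self.compounds):
            if c.ki_um is not None:
                hep_terms[j] = c.unbound_liver_um(y) / c.ki_um
                gut_terms[j] = c.unbound_enterocyte_um(y) / c.ki_um
        for i, c in enumerate(self.compounds):
            hep = 1.0 + clamp_hep + float(np.sum(hep_terms)) - hep_terms[i]
            if self.scenario.gut_ddi:
                gut = 1.0 + clamp_gut + float(np.sum(gut_terms)) - gut_terms[i]
            else:
                gut = 1.0
            c.derivative(y, dy, hep, gut)
        return dy


def build_system(scenario: Scenario) -> ODESystem:
    """Assemble the coupled ODE system and the dose-event schedule.

    The state layout is deterministic: compounds in scenario order, each with
    absorption states, distribution states, then cumulative-elimination
    bookkeeping."""
    compounds: list[_CompoundRuntime] = []
    offset = 0
    pairs = [(scenario.substrate, scenario.substrate_regimen)]
    if scenario.inhibitor is not None:
        pairs.append((scenario.inhibitor, scenario.inhibitor_regimen))
    for drug, regimen in pairs:
        rt = _CompoundRuntime(drug, regimen, scenario.physiology, offset)
        compounds.append(rt)
        offset += rt.n_states
    events = []
    for idx, rt in enumerate(compounds):
        for d in rt.regimen.doses:
            if d.dose_mg > 0:
                events.append((d.time_h, idx, d.dose_mg))
    events.sort(key=lambda e: e[0])
    return ODESystem(
        scenario=scenario, compounds=compounds, n_states=offset, dose_events=events
    )


def _output_grid(scenario: Scenario, system: ODESystem) -> np.ndarray:
    pts = [np.arange(0.0, scenario.horizon_h, scenario.grid_base_h)]
    for t, _, _ in system.dose_events:
        pts.append(t + np.arange(0.0, 3.0, scenario.grid_fine_h))
    pts.append(np.array([scenario.horizon_h]))
    grid = np.unique(np.concatenate(pts))
    return grid[grid <= scenario.horizon_h + 1e-12]


def simulate(scenario: Scenario) -> dict[str, ConcentrationTimeProfile]:
    """Integrate a scenario and return plasma profiles keyed by compound.

    Dosing is applied as state increments at scheduled times; integration is
    piecewise between events with a stiff-capable solver.  The profile log
    records resolved constants and a whole-horizon mass-balance check.
    """
    system = build_system(scenario)
    grid = _output_grid(scenario, system)
    y = np.zeros(system.n_states)

    # segment boundaries: dose times + horizon
    times = sorted({t for t, _, _ in system.dose_events} | {0.0, scenario.horizon_h})
    times = [t for t in times if t <= scenario.horizon_h]
    if times[-1] < scenario.horizon_h:
        times.append(scenario.horizon_h)

    conc = {c.drug.name: np.zeros_like(grid) for c in system.compounds}
    filled = np.zeros_like(grid, dtype=bool)

    solver = scenario.solver
    for k, t0 in enumerate(times[:-1]):
        for t_ev, idx, mg in system.dose_events:
            if abs(t_ev - t0) < 1e-12:
                system.compounds[idx].apply_dose(y, mg)
        t1 = times[k + 1]
        sol = solve_ivp(
            system.rhs,
            (t0, t1),
            y,
            method=solver.method,
            rtol=solver.rtol,
            atol=solver.atol,
            max_step=solver.max_step,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed in [{t0}, {t1}] h; last accepted time "
                f"{sol.t[-1]:.4f} h: {sol.message}"
            )
        sel = (grid >= t0 - 1e-12) & (grid <= t1 + 1e-12) & ~filled
        if np.any(sel):
            ys = sol.sol(grid[sel])
            for c in system.compounds:
                if c.full_layout is not None:
                    cp = ys[c.dist_slice][0] / V_VENOUS_L / c.drug.blood_plasma_ratio
                else:
                    cp = ys[c.dist_slice][0] / c.minimal_layout.v_systemic_l
                conc[c.drug.name][sel] = cp
            filled |= sel
        y = sol.y[:, -1]

    profiles: dict[str, ConcentrationTimeProfile] = {}
    for c in system.compounds:
        administered = sum(d.dose_mg for d in c.regimen.doses)
        eliminated = (
            y[c.i_elim_hep] + y[c.i_elim_ren] + y[c.i_elim_gut]
        )
        remaining = c.body_amount_mg(y) + float(np.sum(y[c.abs_slice]))
        balance = (
            eliminated + remaining + y[c.i_transit_out] + c.unabsorbed_mg
        )
        log = {
            "compound": c.drug.name,
            "distribution_model": c.drug.distribution_model,
            "absorption_model": c.drug.absorption_model,
            "kp_method": c.drug.distribution.kp_method,
            "kp_scalar": c.drug.distribution.kp_scalar,
            "kp": {tp.tissue: round(tp.kp, 6) for tp in c.kp_set},
            "vss_l": round(
                c.full_layout.vss_l if c.full_layout else c.minimal_layout.vss_l, 3
            ),
            "fg_baseline": round(c.fg(1.0), 5),
            "hepatic_clint_u_l_h": round(c.cl.total_hepatic_clint_l_h, 4),
            "renal_cl_l_h": c.cl.renal_l_h,
            "administered_mg": administered,
            "mass_balance_recovered_mg": round(float(balance), 6),
            "mass_balance_rel_error": (
                round(abs(balance - administered) / administered, 8)
                if administered > 0
                else 0.0
            ),
            "solver": {"method": solver.method, "rtol": solver.rtol, "atol": solver.atol},
            "gut_ddi": scenario.gut_ddi,
            "horizon_h": scenario.horizon_h,
        }
        profiles[c.drug.name] = ConcentrationTimeProfile(
            compound=c.drug.name,
            times_h=grid.copy(),
            conc_ng_ml=np.maximum(conc[c.drug.name], 0.0) * 1000.0,
            log=log,
        )
    return profiles


@dataclass(frozen=True)
class IntervalMetrics:
    cmax_ng_ml: float
    tmax_h: float            # relative to the interval start
    auc_tau_ng_h_ml: float
    interval: tuple[float, float]
    accumulation_index: float


def steady_state_metrics(
    profile: ConcentrationTimeProfile, regimen: Regimen
) -> IntervalMetrics:
    """Summaries over the final dosing interval of a multiple-dose regimen.

    Requires at least two completed intervals; the accumulation index is the
    final-interval AUC over the first-interval AUC.
    """
    from .pk_metrics import auc_trapezoid, cmax_tmax

    tau = regimen.dosing_interval_h()
    if tau is None or len(regimen.doses) < 2:
        raise ValueError("steady-state metrics require at least two doses")
    t_last = regimen.last_dose_time_h
    t_end = t_last + tau
    if profile.times_h[-1] < t_end - 1e-9:
        raise ValueError("profile does not cover the final dosing interval")
    last = profile.window(t_last, t_end)
    first_tau = regimen.doses[1].time_h - regimen.doses[0].time_h
    first = profile.window(regimen.doses[0].time_h, regimen.doses[0].time_h + first_tau)
    cmax, tmax = cmax_tmax(last.times_h, last.conc_ng_ml)
    auc_last = auc_trapezoid(last.times_h, last.conc_ng_ml)
    auc_first = auc_trapezoid(first.times_h, first.conc_ng_ml)
    return IntervalMetrics(
        cmax_ng_ml=cmax,
        tmax_h=tmax - t_last,
        auc_tau_ng_h_ml=auc_last,
        interval=(t_last, t_end),
        accumulation_index=auc_last / auc_first if auc_first > 0 else math.nan,
    )
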