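"""IVIVE clearance scaling, well-stirred liver coupling and CYP3A4 inhibition.

In-vitro intrinsic clearances are scaled to whole-liver values through the
microsomal protein content (MPPGL x liver weight) and, for recombinant-enzyme
data, the hepatic CYP3A4 abundance.  Hepatic elimination in the dynamic engine
acts on the unbound drug concentration in the liver compartment, which at
steady state reproduces the well-stirred model implemented here in closed
form.  Reversible competitive inhibition divides the CYP3A4-pathway intrinsic
clearance (equivalently multiplies Km) by 1 + I_u/Ki.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import units
from .params import (
    DrugParameters,
    EliminationPathway,
    LinearClintHLM,
    LinearClintRCYP,
    Physiology,
    SaturableRCYP,
    SystemicRenal,
)


@dataclass(frozen=True)
class LinearPathway:
    """Whole-liver unbound intrinsic clearance, L/h."""

    clint_l_h: float
    is_cyp3a4: bool


@dataclass(frozen=True)
class SaturablePathway:
    """Whole-liver Michaelis-Menten pathway; Vmax in mg/h, Km in mg/L
    (converted from µM with the compound's molecular weight)."""

    vmax_mg_h: float
    km_mg_l: float
    is_cyp3a4: bool

    @property
    def clint_l_h(self) -> float:
        """Low-concentration limit Vmax/Km."""
        return self.vmax_mg_h / self.km_mg_l


@dataclass(frozen=True)
class ClearanceModel:
    """Resolved whole-body clearance terms for one compound."""

    linear: tuple[LinearPathway, ...] = ()
    saturable: tuple[SaturablePathway, ...] = ()
    renal_l_h: float = 0.0

    @property
    def total_hepatic_clint_l_h(self) -> float:
        """Total hepatic unbound intrinsic clearance at baseline (linear
        regime; saturable pathways enter as Vmax/Km)."""
        return sum(p.clint_l_h for p in self.linear) + sum(
            p.clint_l_h for p in self.saturable
        )

    def hepatic_elimination_rate_mg_h(
        self, cu_liver_mg_l: float, inhibition_factor: float = 1.0
    ) -> float:
        """Instantaneous hepatic elimination at an unbound liver concentration
        (plasma-referenced).  ``inhibition_factor`` = 1 + I_u/Ki applies to
        CYP3A4 pathways only."""
        rate = 0.0
        for p in self.linear:
            f = inhibition_factor if p.is_cyp3a4 else 1.0
            rate += (p.clint_l_h / f) * cu_liver_mg_l
        for p in self.saturable:
            f = inhibition_factor if p.is_cyp3a4 else 1.0
            rate += p.vmax_mg_h * cu_liver_mg_l / (p.km_mg_l * f + cu_liver_mg_l)
        return rate


def scale_clint(
    pathway: EliminationPathway,
    physiology: Physiology,
    molecular_weight: float,
    rcyp_isef: float = 1.0,
) -> LinearPathway | SaturablePathway | float:
    """Scale one elimination pathway to whole-organ terms.

    Returns a :class:`LinearPathway` (L/h), a :class:`SaturablePathway`
    (mg/h, mg/L), or — for a renal route — the plasma clearance in L/h.
    ``rcyp_isef`` scales recombinant-enzyme activities (linear CLint and
    Vmax) to the microsomal/in-vivo system.
    """
    k = pathway.kinetics
    if isinstance(k, SystemicRenal):
        return k.systemic_renal
    if isinstance(k, LinearClintHLM):
        cl = units.clint_hlm_to_whole_liver(
            k.linear_clint_hlm, physiology.mppgl_mg_per_g, physiology.liver_weight_g
        )
        return LinearPathway(clint_l_h=cl, is_cyp3a4=pathway.is_cyp3a4)
    if isinstance(k, LinearClintRCYP):
        cl = rcyp_isef * units.clint_rcyp_to_whole_liver(
            k.linear_clint_rcyp,
            physiology.cyp3a4_hepatic_abundance_pmol_mg,
            physiology.mppgl_mg_per_g,
            physiology.liver_weight_g,
        )
        return LinearPathway(clint_l_h=cl, is_cyp3a4=pathway.is_cyp3a4)
    if isinstance(k, SaturableRCYP):
        vmax = rcyp_isef * units.vmax_rcyp_to_whole_liver_mg_h(
            k.vmax_pmol_min_pmol,
            physiology.cyp3a4_hepatic_abundance_pmol_mg,
            physiology.mppgl_mg_per_g,
            physiology.liver_weight_g,
            molecular_weight,
        )
        km = units.um_to_mg_per_l(k.km_um, molecular_weight)
        return SaturablePathway(vmax_mg_h=vmax, km_mg_l=km, is_cyp3a4=pathway.is_cyp3a4)
    raise ValueError(f"unrecognized kinetics {type(k).__name__}")


def build_clearance_model(drug: DrugParameters, physiology: Physiology) -> ClearanceModel:
    linear: list[LinearPathway] = []
    saturable: list[SaturablePathway] = []
    renal = 0.0
    for pw in drug.elimination_pathways:
        scaled = scale_clint(
            pw, physiology, drug.molecular_weight, drug.metabolism.rcyp_isef
        )
        if isinstance(scaled, LinearPathway):
            linear.append(scaled)
        elif isinstance(scaled, SaturablePathway):
            saturable.append(scaled)
        else:
            renal += scaled
    return ClearanceModel(linear=tuple(linear), saturable=tuple(saturable), renal_l_h=renal)


def competitive_inhibition_factor(i_unbound_um: float, ki_um: float) -> float:
    """Reversible competitive inhibition divisor (1 + I_u/Ki)."""
    if ki_um <= 0:
        raise ValueError("Ki must be positive")
    if i_unbound_um < 0:
        raise ValueError("inhibitor concentration must be non-negative")
    return 1.0 + i_unbound_um / ki_um


def hepatic_clearance_well_stirred(
    clint_u_total_l_h: float, fu_plasma: float, blood_plasma_ratio: float, q_h_l_h: float
) -> float:
    """Well-stirred hepatic blood clearance,
    CLh = Qh·fu_b·CLint_u / (Qh + fu_b·CLint_u), with fu_b = fup/Rbp."""
    if clint_u_total_l_h < 0:
        raise ValueError("CLint must be non-negative")
    fu_b = fu_plasma / blood_plasma_ratio
    x = fu_b * clint_u_total_l_h
    return q_h_l_h * x / (q_h_l_h + x)


def reverse_well_stirred_clint(
    cl_blood_l_h: float, fu_plasma: float, blood_plasma_ratio: float, q_h_l_h: float
) -> float:
    """Back-calculate the unbound intrinsic clearance that yields a given
    well-stirred hepatic blood clearance (used to convert an observed systemic
    clearance into a microsomal input when the in-vitro value is missing)."""
    if not 0 <= cl_blood_l_h < q_h_l_h:
        raise ValueError("blood clearance must lie in [0, Qh)")
    fu_b = fu_plasma / blood_plasma_ratio
    return q_h_l_h * cl_blood_l_h / ((q_h_l_h - cl_blood_l_h) * fu_b)


def fm_cyp3a4(model: ClearanceModel) -> float:
    """Fraction of baseline hepatic intrinsic clearance carried by CYP3A4
    (saturable pathways enter at their linear limit Vmax/Km)."""
    total = model.total_hepatic_clint_l_h
    if total <= 0:
        return 0.0
    via_3a4 = sum(p.clint_l_h for p in model.linear if p.is_cyp3a4) + sum(
        p.clint_l_h for p in model.saturable if p.is_cyp3a4
    )
    return via_3a4 / total


def gut_cyp3a4_clint_l_h(drug: DrugParameters, physiology: Physiology) -> float:
    """Whole-small-intestine CYP3A4 intrinsic clearance for the Qgut model.

    Per-pmol intrinsic clearance is taken directly from recombinant-enzyme
    pathways, from microsomal CYP3A4 pathways via the hepatic abundance, and
    from saturable pathways at their linear limit; scaled by the total gut
    CYP3A4 content.
    """
    isef = drug.metabolism.rcyp_isef
    per_pmol = 0.0  # µL/min/pmol
    for pw in drug.elimination_pathways:
        if not pw.is_cyp3a4:
            continue
        k = pw.kinetics
        if isinstance(k, LinearClintRCYP):
            per_pmol += isef * k.linear_clint_rcyp
        elif isinstance(k, LinearClintHLM):
            per_pmol += k.linear_clint_hlm / physiology.cyp3a4_hepatic_abundance_pmol_mg
        elif isinstance(k, SaturableRCYP):
            per_pmol += isef * k.vmax_pmol_min_pmol / k.km_um
    gut_pmol = physiology.cyp3a4_gut_total_nmol * 1000.0
    return per_pmol * gut_pmol * units.UL_PER_MIN_TO_L_PER_H


def gut_cyp3a4_km_um(drug: DrugParameters) -> float | None:
    """Saturation constant for gut-wall CYP3A4 metabolism: the Km of the
    compound's saturable CYP3A4 pathway, or None when metabolism is linear."""
    kms = [
        pw.kinetics.km_um
        for pw in drug.elimination_pathways
        if pw.is_cyp3a4 and isinstance(pw.kinetics, SaturableRCYP)
    ]
    return min(kms) if kms else None
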