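"""Oral absorption models.

Two absorption descriptions are supported:

* **first_order** — the dose enters a single absorbable depot (scaled by the
  absorbed fraction ``fa``) and permeates with rate constant
  ka = 2·Peff/r (cylindrical small intestine).
* **segmented_gi** — a dissolution/transit chain (stomach, duodenum, two
  jejunal and two ileal segments, colon) with Noyes–Whitney dissolution,
  pH-dependent solubility of ionizable bases, first-order inter-segment
  transit and permeation of dissolved drug at 2·Peff/r per segment
  (down-weighted in the colon).

Permeated drug passes the enterocytes, where a fraction 1 − Fg is lost to
gut-wall CYP3A4 metabolism; Fg follows the Qgut model and responds to
competitive inhibition by a co-administered triazole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .elimination import gut_cyp3a4_clint_l_h
from .params import DrugParameters, Physiology, fraction_unionized

#: aqueous diffusion coefficient used by the dissolution term, cm^2/h
DIFFUSION_CM2_H = 5.0e-6 * 3600.0
#: particle true density, g/cm^3
PARTICLE_DENSITY_G_CM3 = 1.2
#: upper bounds keeping the dissolution term non-stiff / physical
MAX_DISSOLUTION_RATE_PER_H = 1000.0
MAX_PH_SOLUBILITY_BOOST = 1000.0


def first_order_ka(drug: DrugParameters, physiology: Physiology) -> float:
    """First-order absorption rate constant, 1/h.

    Uses the explicit override when the compound file provides one, otherwise
    ka = 2·Peff / intestinal radius.
    """
    if drug.absorption.ka_override_per_h is not None:
        return drug.absorption.ka_override_per_h
    if drug.permeability is None:  # pragma: no cover - schema forbids this
        raise ValueError(f"{drug.name}: no permeability and no ka override")
    return units.ka_from_peff(drug.permeability.peff_cm_s(), physiology.intestinal_radius_cm)


def effective_solubility_mg_ml(drug: DrugParameters, pH: float) -> float:
    """pH-adjusted solubility of an ionizable compound: the intrinsic value
    divided by the un-ionized fraction, capped at a 1000-fold gain."""
    if drug.solubility_mg_ml is None:
        raise ValueError(f"{drug.name}: no solubility available")
    boost = min(1.0 / fraction_unionized(drug.ionization, pH), MAX_PH_SOLUBILITY_BOOST)
    return drug.solubility_mg_ml * boost


def dissolution_rate(
    undissolved_mg: float,
    solubility_mg_ml: float,
    dissolved_conc_mg_ml: float,
    segment_volume_ml: float,
    particle_radius_um: float = 10.0,
) -> float:
    """Noyes–Whitney dissolution rate, mg/h.

    First-order in remaining solid with a saturation brake:
    rate = k_d · M_undissolved · max(0, 1 − C/Cs), where
    k_d = 3·D·Cs / (ρ·r²) for monodisperse spheres with a diffusion layer of
    one particle radius.  Zero when the segment is saturated or the solid is
    exhausted; never drives the dissolved amount negative.
    """
    if undissolved_mg <= 0 or solubility_mg_ml <= 0:
        return 0.0
    r_cm = particle_radius_um * 1.0e-4
    cs_g_cm3 = solubility_mg_ml * 1.0e-3
    kd = 3.0 * DIFFUSION_CM2_H * cs_g_cm3 / (PARTICLE_DENSITY_G_CM3 * r_cm**2)
    kd = min(kd, MAX_DISSOLUTION_RATE_PER_H)
    saturation = max(0.0, 1.0 - dissolved_conc_mg_ml / solubility_mg_ml)
    return kd * undissolved_mg * saturation


@dataclass
class AbsorptionState:
    """Per-segment mass inventory of the segmented model (mg)."""

    undissolved: np.ndarray
    dissolved: np.ndarray
    enterocyte_absorbed: float = 0.0
    transited_out: float = 0.0

    def total_mass(self) -> float:
        return (
            float(self.undissolved.sum())
            + float(self.dissolved.sum())
            + self.enterocyte_absorbed
            + self.transited_out
        )


class SegmentedGIModel:
    """Precomputed constants and derivative for the dissolution–transit chain."""

    def __init__(self, drug: DrugParameters, physiology: Physiology):
        self.drug = drug
        self.segments = physiology.gi_segments
        self.n = len(self.segments)
        self.kt = np.array([1.0 / s.transit_time_h for s in self.segments])
        self.volumes_ml = np.array([s.volume_ml for s in self.segments])
        self.cs_mg_ml = np.array(
            [effective_solubility_mg_ml(drug, s.pH) for s in self.segments]
        )
        ka = units.ka_from_peff(
            drug.permeability.peff_cm_s(), physiology.intestinal_radius_cm
        )
        kperm = np.full(self.n, ka)
        for i, s in enumerate(self.segments):
            if s.name == "stomach":
                kperm[i] = 0.0
            elif s.name == "colon":
                kperm[i] = ka * drug.absorption.colon_permeation_scale
        self.kperm = kperm
        self.particle_radius_um = drug.absorption.particle_radius_um

    @property
    def n_states(self) -> int:
        return 2 * self.n

    def derivative(
        self, solid: np.ndarray, dissolved: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, float, float]:
        """Return (dSolid/dt, dDissolved/dt, permeation flux mg/h,
        transit-out rate mg/h)."""
        solid = np.maximum(solid, 0.0)
        dissolved = np.maximum(dissolved, 0.0)
        diss = np.array(
            [
                dissolution_rate(
                    solid[i],
                    self.cs_mg_ml[i],
                    dissolved[i] / self.volumes_ml[i],
                    self.volumes_ml[i],
                    self.particle_radius_um,
                )
                for i in range(self.n)
            ]
        )
        perm = self.kperm * dissolved
        ds = -diss - self.kt * solid
        dd = diss - self.kt * dissolved - perm
        # transit chain: segment i feeds i+1
        ds[1:] += self.kt[:-1] * solid[:-1]
        dd[1:] += self.kt[:-1] * dissolved[:-1]
        transit_out = self.kt[-1] * (solid[-1] + dissolved[-1])
        return ds, dd, float(perm.sum()), float(transit_out)


def gi_transit_step(
    state: AbsorptionState, drug: DrugParameters, physiology: Physiology
) -> AbsorptionState:
    """Derivative of an :class:`AbsorptionState` (mass balance closes: the
    component rates sum to zero)."""
    model = SegmentedGIModel(drug, physiology)
    ds, dd, perm, out = model.derivative(state.undissolved, state.dissolved)
    return AbsorptionState(
        undissolved=ds, dissolved=dd, enterocyte_absorbed=perm, transited_out=out
    )


def gut_extraction_fraction(
    drug: DrugParameters,
    physiology: Physiology,
    gut_inhibition_factor: float = 1.0,
) -> float:
    """Fraction of absorbed drug escaping gut-wall CYP3A4 metabolism (Qgut
    model):

        Fg = Qgut / (Qgut + fu_gut · CLint_gut,u / (1 + I_u/Ki))

    with Qgut = Qvilli·CLperm / (Qvilli + CLperm).  ``gut_inhibition_factor``
    is the competitive term 1 + Σ I_u/Ki from co-administered inhibitors;
    drugs with no CYP3A4 pathway have Fg = 1.
    """
    clint_gut = gut_cyp3a4_clint_l_h(drug, physiology)
    if clint_gut <= 0:
        return 1.0
    clperm = units.permeation_clearance_l_h(
        drug.permeability.peff_cm_s(), physiology.intestinal_surface_area_cm2
    )
    qvilli = physiology.villous_blood_flow_l_h
    qgut = qvilli * clperm / (qvilli + clperm)
    inhibited = drug.fu_gut_effective * clint_gut / gut_inhibition_factor
    return qgut / (qgut + inhibited)
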