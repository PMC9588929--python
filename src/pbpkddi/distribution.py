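"""Tissue distribution: partition-coefficient prediction and model layouts.

Two Kp prediction methods are provided, both driven by the bundled tissue
composition table:

* ``rodgers_rowland`` — mechanistic tissue-composition equations for neutral
  compounds and weak bases (all five bundled compounds have base pKa ≤ 5.8 and
  are predominantly un-ionized at physiological pH, so the moderate/weak-base
  class applies): partitioning into tissue water with an
  ionization correction, into neutral lipid and phospholipid, plus reversible
  binding to extracellular albumin scaled from the measured plasma unbound
  fraction.
* ``poulin_theil_berezhkovskiy`` — lipid/water distribution with the
  Berezhkovskiy tissue unbound fraction correction.

Adipose partitioning uses a vegetable-oil:water surrogate for the
octanol:water partition coefficient, log Dvo = 1.115·logP − 1.35, in both
methods (standard practice; octanol over-predicts storage-lipid affinity).

Predicted Kp values may be scaled by a per-compound ``kp_scalar`` (a normal
compound-file calibration handle when a measured distribution volume is
available); the scalar is recorded in the scenario log.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import yaml

from .params import DrugParameters, Physiology, ionized_over_unionized

_COMPOSITION_FILE = Path(__file__).parent / "data" / "tissue_composition.yaml"

KP_METHODS = ("rodgers_rowland", "poulin_theil_berezhkovskiy")


@dataclass(frozen=True)
class TissuePartition:
    tissue: str
    kp: float

    def __post_init__(self) -> None:
        if self.kp <= 0:
            raise ValueError(f"Kp must be positive (tissue {self.tissue})")


@lru_cache(maxsize=1)
def tissue_composition() -> dict:
    with open(_COMPOSITION_FILE) as fh:
        return yaml.safe_load(fh)


def _adipose_partition(logp: float) -> float:
    """Vegetable-oil:water partition surrogate for storage lipid."""
    return 10.0 ** (1.115 * logp - 1.35)


def _plasma_lipid_term(p: float, comp: dict) -> float:
    pl = comp["plasma"]
    return p * pl["f_nl"] + (0.3 * p + 0.7) * pl["f_np"]


def _kp_rodgers_rowland(drug: DrugParameters, tissue: str, comp: dict) -> float:
    t = comp["tissues"][tissue]
    ph_p = comp["plasma_ph"]
    ph_iw = comp["intracellular_ph"]
    p = 10.0 ** drug.logP
    p_t = _adipose_partition(drug.logP) if tissue in ("adipose", "bone") else p

    # ionization terms (1 + Σ10^±(pKa−pH)); weak-base/neutral class
    y_p = 1.0 + ionized_over_unionized(drug.ionization, ph_p)
    y_iw = 1.0 + ionized_over_unionized(drug.ionization, ph_iw)

    lipid = (p_t * t["f_nl"] + (0.3 * p_t + 0.7) * t["f_np"]) / y_p

    # extracellular protein (albumin) association constant, inferred from fup
    ka_prp = 1.0 / drug.fu_plasma - 1.0 - _plasma_lipid_term(p, comp) / y_p
    protein = max(ka_prp, 0.0) * t["alb_ratio"]
    if tissue in ("adipose", "bone"):
        protein = 0.0  # negligible extracellular protein in storage tissue

    kpu = t["f_ew"] + (y_iw / y_p) * t["f_iw"] + lipid + protein
    return max(kpu * drug.fu_plasma, 1.0e-6)


def _kp_poulin_theil(drug: DrugParameters, tissue: str, comp: dict) -> float:
    t = comp["tissues"][tissue]
    pl = comp["plasma"]
    p = 10.0 ** drug.logP
    p_t = _adipose_partition(drug.logP) if tissue in ("adipose", "bone") else p

    f_w_t = t["f_ew"] + t["f_iw"]
    num = p_t * (t["f_nl"] + 0.3 * t["f_np"]) + (f_w_t + 0.7 * t["f_np"])
    den = p * (pl["f_nl"] + 0.3 * pl["f_np"]) + (pl["f_water"] + 0.7 * pl["f_np"])

    if tissue in ("adipose", "bone"):
        # storage tissue: no macromolecular binding term, unbound ratio = fup
        return max((num / den) * drug.fu_plasma, 1.0e-6)
    # Berezhkovskiy tissue unbound fraction from the albumin ratio
    fu_t = 1.0 / (1.0 + ((1.0 - drug.fu_plasma) / drug.fu_plasma) * t["alb_ratio"])
    return max((num / den) * drug.fu_plasma / fu_t, 1.0e-6)


def predict_kp_set(
    drug: DrugParameters,
    physiology: Physiology,
    method: str | None = None,
) -> list[TissuePartition]:
    """Predict one tissue:plasma partition coefficient per configured tissue.

    Deterministic for fixed inputs.  The per-compound ``kp_scalar`` is applied
    to every tissue.
    """
    method = method or drug.distribution.kp_method
    if method not in KP_METHODS:
        raise ValueError(f"unknown Kp method {method!r}; choose from {KP_METHODS}")
    comp = tissue_composition()
    fn = _kp_rodgers_rowland if method == "rodgers_rowland" else _kp_poulin_theil
    out = []
    for tc in physiology.tissue_compartments:
        name = tc.name if tc.name in comp["tissues"] else "rest"
        kp = fn(drug, name, comp) * drug.distribution.kp_scalar
        out.append(TissuePartition(tissue=tc.name, kp=kp))
    return out


def vss_from_kp(kp_set: list[TissuePartition], physiology: Physiology) -> float:
    """Plasma-referenced steady-state volume: Vss = Vplasma + Σ Kp_t · V_t."""
    vols = {t.name: t.volume_l for t in physiology.tissue_compartments}
    return physiology.plasma_volume_l + sum(tp.kp * vols[tp.tissue] for tp in kp_set)


#: slowly perfused tissues lumped into the optional peripheral compartment
PERIPHERAL_TISSUES = ("adipose", "muscle", "bone")


@dataclass(frozen=True)
class MinimalLayout:
    """Minimal PBPK: one systemic compartment plus a mechanistic well-stirred
    liver wired through the hepatic blood flow (portal inlet receives the
    absorbed drug flux).  Optionally a flow-limited peripheral compartment
    lumping the slowly perfused tissues."""

    vss_l: float
    v_systemic_l: float
    v_liver_l: float
    kp_liver: float
    v_peripheral_l: float = 0.0
    q_peripheral_l_h: float = 0.0   # plasma-referenced distribution clearance

    @property
    def has_peripheral(self) -> bool:
        return self.v_peripheral_l > 0


def minimal_pbpk_volumes(
    drug: DrugParameters,
    kp_set: list[TissuePartition],
    physiology: Physiology,
) -> MinimalLayout:
    """Compartment volumes for the minimal model.

    The systemic volume is the Kp-derived (or overridden) Vss less the liver's
    share, floored at the plasma volume.  With the peripheral option, the
    Kp-weighted volume of the slowly perfused tissues is split off into a
    compartment whose uptake is limited by their summed blood flow.
    """
    kp_liver = next(tp.kp for tp in kp_set if tp.tissue == "liver")
    vss = drug.distribution.vss_override_l or vss_from_kp(kp_set, physiology)
    v_liver = physiology.liver_volume_l

    v_per = 0.0
    q_per = 0.0
    if drug.distribution.peripheral_compartment:
        kp = {tp.tissue: tp.kp for tp in kp_set}
        scale = vss / vss_from_kp(kp_set, physiology)  # honor a Vss override
        for name in PERIPHERAL_TISSUES:
            t = physiology.tissue(name)
            v_per += kp[name] * t.volume_l * scale
            q_per += t.blood_flow_l_h
        q_per *= drug.blood_plasma_ratio  # blood flow limit in plasma terms

    v_sys = max(vss - kp_liver * v_liver - v_per, physiology.plasma_volume_l)
    return MinimalLayout(
        vss_l=vss,
        v_systemic_l=v_sys,
        v_liver_l=v_liver,
        kp_liver=kp_liver,
        v_peripheral_l=v_per,
        q_peripheral_l_h=q_per,
    )


@dataclass(frozen=True)
class FullLayout:
    """Perfusion-limited whole-body layout: lung in series between venous and
    arterial pools; liver receives hepatic artery plus the portal vein
    draining the gut compartment."""

    tissues: tuple[str, ...]          # perfusion-limited tissues (excl. lung)
    volumes_l: dict
    flows_l_h: dict
    kp: dict
    v_lung_l: float
    kp_lung: float
    cardiac_output_l_h: float

    @property
    def vss_l(self) -> float:
        v = sum(self.kp[t] * self.volumes_l[t] for t in self.tissues)
        return v + self.kp_lung * self.v_lung_l


def full_pbpk_layout(
    drug: DrugParameters,
    kp_set: list[TissuePartition],
    physiology: Physiology,
) -> FullLayout:
    kp = {tp.tissue: tp.kp for tp in kp_set}
    tissues = tuple(
        t.name for t in physiology.tissue_compartments if t.name != "lung"
    )
    volumes = {t.name: t.volume_l for t in physiology.tissue_compartments}
    flows = {t.name: t.blood_flow_l_h for t in physiology.tissue_compartments}
    total_flow = sum(flows[t] for t in tissues)
    if total_flow > physiology.cardiac_output_l_h + 1e-9:
        raise ValueError("tissue blood flows exceed cardiac output")
    return FullLayout(
        tissues=tissues,
        volumes_l={t: volumes[t] for t in tissues},
        flows_l_h={t: flows[t] for t in tissues},
        kp={t: kp[t] for t in tissues},
        v_lung_l=volumes["lung"],
        kp_lung=kp["lung"],
        cardiac_output_l_h=physiology.cardiac_output_l_h,
    )
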