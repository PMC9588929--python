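"""Drug, physiology and regimen parameter definitions, validation and I/O.

Every compound is described by a :class:`DrugParameters` document (shipped as
YAML under ``pbpkddi/data/``) holding the physicochemical properties,
permeability, in-vitro clearances and — for enzyme inhibitors — the reversible
competitive inhibition constant Ki.  System (drug-independent) parameters live
in :class:`Physiology`; the healthy-adult default set is returned by
:func:`default_physiology` and its constants are documented in
``docs/methods.md``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import units

SCHEMA_VERSION = "pbpkddi-drug/1"

DATA_DIR = Path(__file__).parent / "data"


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


# ---------------------------------------------------------------------------
# Drug parameters
# ---------------------------------------------------------------------------


class IonizationGroup(_Model):
    """A single ionizable group (monoprotic term of a Henderson–Hasselbalch
    description); diprotic bases carry two entries."""

    type: Literal["base", "acid"]
    pKa: float = Field(gt=0, lt=14)


class Permeability(_Model):
    """Exactly one representation: human jejunal Peff (10^-4 cm/s) or Caco-2
    Papp (10^-6 cm/s, converted internally by a fixed calibration line)."""

    peff_human: Optional[float] = Field(default=None, ge=0)
    papp_caco2: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _exactly_one(self) -> "Permeability":
        if (self.peff_human is None) == (self.papp_caco2 is None):
            raise ValueError(
                "exactly one of peff_human / papp_caco2 must be provided"
            )
        return self

    def peff_1e4_cm_s(self) -> float:
        """Resolved effective permeability in 10^-4 cm/s."""
        if self.peff_human is not None:
            return self.peff_human
        return units.papp_caco2_to_peff(self.papp_caco2)

    def peff_cm_s(self) -> float:
        return self.peff_1e4_cm_s() * 1.0e-4


class LinearClintHLM(_Model):
    """Linear intrinsic clearance normalized to microsomal protein
    (µL/min/mg)."""

    linear_clint_hlm: float = Field(ge=0)


class LinearClintRCYP(_Model):
    """Linear intrinsic clearance normalized to recombinant enzyme
    (µL/min/pmol)."""

    linear_clint_rcyp: float = Field(ge=0)


class SaturableRCYP(_Model):
    """Michaelis–Menten kinetics on a recombinant-enzyme basis."""

    km_um: float = Field(gt=0)
    vmax_pmol_min_pmol: float = Field(ge=0)


class SystemicRenal(_Model):
    """Renal clearance referenced to plasma, L/h."""

    systemic_renal: float = Field(ge=0)


Kinetics = Union[LinearClintHLM, LinearClintRCYP, SaturableRCYP, SystemicRenal]


class EliminationPathway(_Model):
    route: Literal["hepatic_CYP3A4", "hepatic_additional", "renal"]
    kinetics: Kinetics

    @model_validator(mode="after")
    def _route_kinetics_consistent(self) -> "EliminationPathway":
        if self.route == "renal" and not isinstance(self.kinetics, SystemicRenal):
            raise ValueError("renal pathway requires systemic_renal kinetics")
        if self.route != "renal" and isinstance(self.kinetics, SystemicRenal):
            raise ValueError("systemic_renal kinetics only valid on a renal route")
        return self

    @property
    def is_cyp3a4(self) -> bool:
        return self.route == "hepatic_CYP3A4"


class InteractionParameters(_Model):
    """Reversible competitive inhibition of a metabolic enzyme, applied to the
    unbound inhibitor concentration at the enzyme site."""

    target_enzyme: Literal["CYP3A4"] = "CYP3A4"
    ki_um: float = Field(gt=0)
    basis: Literal["unbound"] = "unbound"


class AbsorptionSettings(_Model):
    """Optional absorption-model tuning.

    ``fa`` scales the fraction of each dose entering the absorbable depot
    (first-order model only; used for solubility-limited compounds described
    with a documented constant instead of the segmented GI model).
    ``particle_radius_um`` feeds the Noyes–Whitney dissolution rate of the
    segmented model.  ``colon_permeation_scale`` down-weights colonic
    absorptive permeability relative to the small intestine.
    """

    fa: float = Field(default=1.0, gt=0, le=1.0)
    ka_override_per_h: Optional[float] = Field(default=None, ge=0)
    particle_radius_um: float = Field(default=10.0, gt=0)
    colon_permeation_scale: float = Field(default=0.1, ge=0, le=1.0)


class MetabolismSettings(_Model):
    """Optional metabolism-model tuning.

    ``rcyp_isef`` is the inter-system extrapolation factor applied to
    recombinant-enzyme clearances (linear CLint and Vmax) when scaling to the
    whole liver and gut — the standard calibration handle reconciling
    recombinant-system activity with microsomal/in-vivo activity.
    """

    rcyp_isef: float = Field(default=1.0, gt=0)


class DistributionSettings(_Model):
    """Optional distribution-model tuning.

    ``kp_scalar`` multiplies every predicted tissue:plasma partition
    coefficient (the usual compound-file calibration handle when a measured
    steady-state volume is known); ``vss_override_l`` pins the minimal-model
    distribution volume directly.
    """

    kp_method: Literal["rodgers_rowland", "poulin_theil_berezhkovskiy"] = (
        "rodgers_rowland"
    )
    kp_scalar: float = Field(default=1.0, gt=0)
    vss_override_l: Optional[float] = Field(default=None, gt=0)
    # minimal model only: lump the slowly perfused tissues (adipose, muscle,
    # bone) into a flow-limited peripheral compartment instead of the single
    # systemic pool, giving the model a distribution phase
    peripheral_compartment: bool = False


class DrugParameters(_Model):
    schema_version: str = Field(default=SCHEMA_VERSION, alias="schema")
    name: str
    molecular_weight: float = Field(gt=0)
    ionization: list[IonizationGroup] = Field(default_factory=list)
    logP: float
    solubility_mg_ml: Optional[float] = Field(default=None, gt=0)
    solubility_assumed: bool = False
    fu_plasma: float = Field(gt=0, le=1.0)
    fu_gut: Optional[float] = Field(default=None, gt=0, le=1.0)
    blood_plasma_ratio: float = Field(gt=0)
    permeability: Permeability
    absorption_model: Literal["first_order", "segmented_gi"]
    distribution_model: Literal["minimal", "full"]
    elimination_pathways: list[EliminationPathway] = Field(min_length=1)
    interaction: Optional[InteractionParameters] = None
    absorption: AbsorptionSettings = Field(default_factory=AbsorptionSettings)
    distribution: DistributionSettings = Field(default_factory=DistributionSettings)
    metabolism: MetabolismSettings = Field(default_factory=MetabolismSettings)

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    @model_validator(mode="after")
    def _invariants(self) -> "DrugParameters":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema version {self.schema_version!r}; "
                f"expected {SCHEMA_VERSION!r}"
            )
        if self.absorption_model == "segmented_gi" and self.solubility_mg_ml is None:
            raise ValueError("segmented_gi absorption requires a solubility")
        return self

    @property
    def fu_gut_effective(self) -> float:
        """Unbound fraction in enterocytes; defaults to fu_plasma when the
        source data does not report it."""
        return self.fu_gut if self.fu_gut is not None else self.fu_plasma

    @property
    def fu_blood(self) -> float:
        """Unbound fraction in blood, fu,b = fup / Rbp."""
        return self.fu_plasma / self.blood_plasma_ratio

    def has_cyp3a4_pathway(self) -> bool:
        return any(p.is_cyp3a4 for p in self.elimination_pathways)

    def to_document(self) -> dict:
        """Round-trippable plain-dict form (suitable for YAML)."""
        return self.model_dump(mode="json", by_alias=True, exclude_none=True)


def load_drug_parameters(source: Union[str, Path, dict]) -> DrugParameters:
    """Load and validate a drug parameter document.

    ``source`` may be a mapping, a path to a YAML file, or the bare name of a
    bundled compound (e.g. ``"zanubrutinib"``).  Unknown keys are rejected and
    all invariants are enforced.
    """
    if isinstance(source, dict):
        return DrugParameters.model_validate(source)
    path = Path(source)
    if not path.suffix and not path.exists():
        candidate = DATA_DIR / f"{path.name}.yaml"
        if candidate.exists():
            path = candidate
    if not path.exists():
        raise FileNotFoundError(f"drug parameter file not found: {source}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return DrugParameters.model_validate(doc)


def bundled_drug_names() -> list[str]:
    return sorted(p.stem for p in DATA_DIR.glob("*.yaml"))


def serialize_drug_parameters(drug: DrugParameters, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(drug.to_document(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Physiology
# ---------------------------------------------------------------------------


class GISegment(_Model):
    name: str
    volume_ml: float = Field(gt=0)
    pH: float = Field(ge=0, le=14)
    transit_time_h: float = Field(gt=0)


class TissueCompartment(_Model):
    name: str
    volume_l: float = Field(gt=0)
    blood_flow_l_h: float = Field(gt=0)


class Physiology(_Model):
    """Healthy-adult system parameters.

    Declared constants (not fitted per compound): organ volumes and blood
    flows follow standard reference-man tables; the IVIVE scaling chain is
    pinned at liver weight 1650 g, MPPGL 40 mg/g, hepatic CYP3A4 abundance
    137 pmol/mg and small-intestinal CYP3A4 70 nmol.
    """

    body_weight_kg: float = Field(default=70.0, gt=0)
    cardiac_output_l_h: float = Field(default=390.0, gt=0)
    hepatic_blood_flow_l_h: float = Field(default=87.0, gt=0)
    portal_vein_flow_l_h: float = Field(default=65.25, gt=0)
    liver_weight_g: float = Field(default=1650.0, gt=0)
    mppgl_mg_per_g: float = Field(default=40.0, gt=0)
    cyp3a4_hepatic_abundance_pmol_mg: float = Field(default=137.0, gt=0)
    cyp3a4_gut_total_nmol: float = Field(default=70.0, gt=0)
    villous_blood_flow_l_h: float = Field(default=18.0, gt=0)
    intestinal_radius_cm: float = Field(default=1.75, gt=0)
    intestinal_surface_area_cm2: float = Field(default=6600.0, gt=0)
    plasma_volume_l: float = Field(default=3.0, gt=0)
    glomerular_filtration_rate_l_h: float = Field(default=6.7, gt=0)
    gi_segments: list[GISegment]
    tissue_compartments: list[TissueCompartment]

    @model_validator(mode="after")
    def _flows_consistent(self) -> "Physiology":
        total = sum(t.blood_flow_l_h for t in self.tissue_compartments if t.name != "lung")
        if total > self.cardiac_output_l_h + 1e-9:
            raise ValueError(
                f"sum of tissue blood flows ({total:.1f} L/h) exceeds cardiac "
                f"output ({self.cardiac_output_l_h:.1f} L/h)"
            )
        if self.portal_vein_flow_l_h >= self.hepatic_blood_flow_l_h:
            raise ValueError("portal vein flow must be below total hepatic flow")
        return self

    @property
    def hepatic_artery_flow_l_h(self) -> float:
        return self.hepatic_blood_flow_l_h - self.portal_vein_flow_l_h

    @property
    def liver_volume_l(self) -> float:
        for t in self.tissue_compartments:
            if t.name == "liver":
                return t.volume_l
        raise ValueError("physiology has no liver compartment")

    def tissue(self, name: str) -> TissueCompartment:
        for t in self.tissue_compartments:
            if t.name == name:
                return t
        raise KeyError(name)


_DEFAULT_GI_SEGMENTS = [
    # stomach + duodenum/jejunum x2/ileum x2 + colon transit chain; the
    # small-intestinal residence sums to ~3.2 h
    GISegment(name="stomach", volume_ml=50.0, pH=1.5, transit_time_h=0.4),
    GISegment(name="duodenum", volume_ml=50.0, pH=6.0, transit_time_h=0.26),
    GISegment(name="jejunum_1", volume_ml=100.0, pH=6.2, transit_time_h=0.95),
    GISegment(name="jejunum_2", volume_ml=100.0, pH=6.4, transit_time_h=0.75),
    GISegment(name="ileum_1", volume_ml=100.0, pH=6.6, transit_time_h=0.60),
    GISegment(name="ileum_2", volume_ml=100.0, pH=6.9, transit_time_h=0.60),
    GISegment(name="colon", volume_ml=300.0, pH=6.8, transit_time_h=12.0),
]

# (name, volume L, blood flow L/h) — reference-man values for a 70-kg adult.
# The gut compartment carries the portal flow; the hepatic artery carries the
# remainder of the total hepatic flow.  "rest" closes the cardiac-output
# balance.
_DEFAULT_TISSUES = [
    ("adipose", 13.5, 15.6),
    ("bone", 10.2, 14.7),
    ("brain", 1.45, 42.0),
    ("gut", 1.65, 65.25),
    ("heart", 0.33, 9.0),
    ("kidney", 0.31, 66.0),
    ("liver", 1.65, 21.75),
    ("muscle", 29.0, 45.0),
    ("skin", 3.4, 18.0),
    ("spleen", 0.19, 6.0),
    ("rest", 4.0, 86.7),
    ("lung", 0.53, 390.0),
]


def default_physiology() -> Physiology:
    """The documented healthy-adult default parameter set."""
    return Physiology(
        gi_segments=list(_DEFAULT_GI_SEGMENTS),
        tissue_compartments=[
            TissueCompartment(name=n, volume_l=v, blood_flow_l_h=q)
            for n, v, q in _DEFAULT_TISSUES
        ],
    )


# ---------------------------------------------------------------------------
# Regimen
# ---------------------------------------------------------------------------


class DoseEvent(_Model):
    dose_mg: float = Field(ge=0)
    time_h: float = Field(ge=0)


class Regimen(_Model):
    """An oral dosing schedule: explicit (dose, time) events, strictly
    increasing in time."""

    compound: str
    route: Literal["oral"] = "oral"
    doses: list[DoseEvent] = Field(min_length=1)

    @model_validator(mode="after")
    def _times_increasing(self) -> "Regimen":
        times = [d.time_h for d in self.doses]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        return self

    @classmethod
    def single(cls, compound: str, dose_mg: float, time_h: float = 0.0) -> "Regimen":
        return cls(compound=compound, doses=[DoseEvent(dose_mg=dose_mg, time_h=time_h)])

    @classmethod
    def repeating(
        cls,
        compound: str,
        dose_mg: float,
        interval_h: float,
        n_doses: int,
        loading: Optional[Sequence[tuple[float, float]]] = None,
        start_h: float = 0.0,
    ) -> "Regimen":
        """Pattern constructor: optional loading doses followed by ``n_doses``
        maintenance doses every ``interval_h`` hours.

        When loading doses are given, the maintenance schedule starts one
        interval after the last loading dose.
        """
        events: list[DoseEvent] = []
        t0 = start_h
        if loading:
            for dose, t in loading:
                events.append(DoseEvent(dose_mg=dose, time_h=t))
            t0 = loading[-1][1] + interval_h
        for i in range(n_doses):
            events.append(DoseEvent(dose_mg=dose_mg, time_h=t0 + i * interval_h))
        return cls(compound=compound, doses=events)

    @property
    def last_dose_time_h(self) -> float:
        return self.doses[-1].time_h

    def dosing_interval_h(self) -> Optional[float]:
        """The trailing inter-dose interval, or None for a single dose."""
        if len(self.doses) < 2:
            return None
        return self.doses[-1].time_h - self.doses[-2].time_h


# ---------------------------------------------------------------------------
# Henderson–Hasselbalch
# ---------------------------------------------------------------------------


def fraction_unionized(ionization: Sequence[IonizationGroup], pH: float) -> float:
    """Fraction of the compound in its un-ionized form at the given pH.

    Monoprotic base: 1 / (1 + 10^(pKa - pH)); acid: 1 / (1 + 10^(pH - pKa)).
    Polyprotic species multiply terms (independent-site approximation).  A
    neutral compound (no ionizable groups) returns 1 at any pH.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    f = 1.0
    for grp in ionization:
        if grp.type == "base":
            f *= 1.0 / (1.0 + 10.0 ** (grp.pKa - pH))
        else:
            f *= 1.0 / (1.0 + 10.0 ** (pH - grp.pKa))
    return f


def ionized_over_unionized(ionization: Sequence[IonizationGroup], pH: float) -> float:
    """Total ionized-to-unionized ratio, Σ 10^±(pKa−pH) over groups."""
    total = 0.0
    for grp in ionization:
        if grp.type == "base":
            total += 10.0 ** (grp.pKa - pH)
        else:
            total += 10.0 ** (pH - grp.pKa)
    return total
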