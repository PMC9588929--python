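"""Synthetic compounds and virtual-population physiology.

The generator draws physiologically plausible drug parameter sets (first-order
absorption, minimal distribution, linear hepatic + renal elimination) and
lognormally perturbed physiologies around the healthy-adult defaults, so that
every pipeline stage — including parameter recovery — can be exercised beyond
the five bundled compounds.  All randomness is owned by a single seed.

Default variability (coefficients of variation) follows common virtual-trial
practice: 30% on intrinsic clearance drivers (MPPGL, enzyme abundance), 20%
on flows and volumes; inhibition constants are not varied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

from .engine import Scenario, simulate
from .params import DrugParameters, Physiology, Regimen, default_physiology

DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "logP": (0.5, 4.5),
    "pKa": (2.0, 7.0),
    "fu_plasma": (0.02, 0.95),
    "blood_plasma_ratio": (0.6, 1.4),
    "solubility_mg_ml": (0.01, 5.0),
    "peff_1e4_cm_s": (0.3, 6.0),
    "clint_hlm_ul_min_mg": (2.0, 150.0),
    "clr_l_h": (0.0, 5.0),
    "ki_um": (0.01, 20.0),
}


@dataclass
class GeneratorSpec:
    seed: int
    n_subjects: int = 1
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    cv_clearance: float = 0.30
    cv_flows_volumes: float = 0.20

    def __post_init__(self) -> None:
        if self.cv_clearance < 0 or self.cv_flows_volumes < 0:
            raise ValueError("CVs must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for key, (lo, hi) in self.ranges.items():
            if not lo <= hi:
                raise ValueError(f"infeasible range for {key}: ({lo}, {hi})")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _uniform(rng: np.random.Generator, rg: tuple[float, float]) -> float:
    return float(rng.uniform(*rg))


def generate_drug(
    spec: GeneratorSpec,
    role: Literal["substrate", "inhibitor"] = "substrate",
    rng: np.random.Generator | None = None,
    cyp3a4_fraction: float | None = None,
) -> DrugParameters:
    """Draw one synthetic compound; inhibitors always carry a Ki.

    ``cyp3a4_fraction`` splits the hepatic intrinsic clearance between a
    CYP3A4 pathway and a non-CYP3A pathway (drawn uniformly when omitted).
    """
    rng = rng or spec.rng()
    r = spec.ranges
    clint = _uniform(rng, r["clint_hlm_ul_min_mg"])
    frac_3a4 = (
        cyp3a4_fraction if cyp3a4_fraction is not None else float(rng.uniform(0.2, 0.9))
    )
    pathways = []
    if frac_3a4 > 0:
        pathways.append(
            {"route": "hepatic_CYP3A4", "kinetics": {"linear_clint_hlm": clint * frac_3a4}}
        )
    if frac_3a4 < 1:
        pathways.append(
            {
                "route": "hepatic_additional",
                "kinetics": {"linear_clint_hlm": clint * (1.0 - frac_3a4)},
            }
        )
    clr = _uniform(rng, r["clr_l_h"])
    if clr > 0:
        pathways.append({"route": "renal", "kinetics": {"systemic_renal": clr}})
    doc = {
        "name": f"synthetic_{role}_{rng.integers(0, 10**9)}",
        "molecular_weight": float(rng.uniform(250.0, 650.0)),
        "ionization": [{"type": "base", "pKa": _uniform(rng, r["pKa"])}],
        "logP": _uniform(rng, r["logP"]),
        "solubility_mg_ml": _uniform(rng, r["solubility_mg_ml"]),
        "fu_plasma": _uniform(rng, r["fu_plasma"]),
        "blood_plasma_ratio": _uniform(rng, r["blood_plasma_ratio"]),
        "permeability": {"peff_human": _uniform(rng, r["peff_1e4_cm_s"])},
        "absorption_model": "first_order",
        "distribution_model": "minimal",
        "elimination_pathways": pathways,
    }
    if role == "inhibitor":
        doc["interaction"] = {"target_enzyme": "CYP3A4", "ki_um": _uniform(rng, r["ki_um"])}
    return DrugParameters.model_validate(doc)


def sample_population(spec: GeneratorSpec) -> list[Physiology]:
    """Lognormal perturbations around the default physiology.

    Per-subject scale factors are applied jointly to flow-like and volume-like
    fields (preserving the flow-balance invariants by construction) and
    independently to the clearance drivers MPPGL and CYP3A4 abundance.
    """
    rng = spec.rng()
    base = default_physiology()
    out: list[Physiology] = []

    def lognorm(cv: float) -> float:
        if cv == 0:
            return 1.0
        sigma = np.sqrt(np.log(1.0 + cv**2))
        return float(rng.lognormal(-0.5 * sigma**2, sigma))

    for _ in range(spec.n_subjects):
        f_flow = lognorm(spec.cv_flows_volumes)
        f_vol = lognorm(spec.cv_flows_volumes)
        f_mppgl = lognorm(spec.cv_clearance)
        f_abund = lognorm(spec.cv_clearance)
        subject = base.model_copy(
            update={
                "cardiac_output_l_h": base.cardiac_output_l_h * f_flow,
                "hepatic_blood_flow_l_h": base.hepatic_blood_flow_l_h * f_flow,
                "portal_vein_flow_l_h": base.portal_vein_flow_l_h * f_flow,
                "villous_blood_flow_l_h": base.villous_blood_flow_l_h * f_flow,
                "glomerular_filtration_rate_l_h": base.glomerular_filtration_rate_l_h
                * f_flow,
                "liver_weight_g": base.liver_weight_g * f_vol,
                "plasma_volume_l": base.plasma_volume_l * f_vol,
                "mppgl_mg_per_g": base.mppgl_mg_per_g * f_mppgl,
                "cyp3a4_hepatic_abundance_pmol_mg": (
                    base.cyp3a4_hepatic_abundance_pmol_mg * f_abund
                ),
                "cyp3a4_gut_total_nmol": base.cyp3a4_gut_total_nmol * f_abund,
                "tissue_compartments": [
                    t.model_copy(
                        update={
                            "volume_l": t.volume_l * f_vol,
                            "blood_flow_l_h": t.blood_flow_l_h * f_flow,
                        }
                    )
                    for t in base.tissue_compartments
                ],
            }
        )
        out.append(subject)
    return out


# ---------------------------------------------------------------------------
# one-compartment reduction and parameter recovery
# ---------------------------------------------------------------------------


def bateman(t: np.ndarray, f_dose_v: float, ka: float, ke: float) -> np.ndarray:
    """Oral one-compartment profile C(t) = (F·D/V)·ka/(ka−ke)·(e^−ke·t − e^−ka·t)."""
    ka = max(ka, 1e-9)
    ke = max(ke, 1e-9)
    if abs(ka - ke) < 1e-9:
        return f_dose_v * ka * t * np.exp(-ka * t)
    return f_dose_v * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


def fit_one_compartment(
    times_h: np.ndarray, conc_mg_l: np.ndarray, dose_mg: float
) -> tuple[float, float, float]:
    """Least-squares fit of the oral one-compartment model.

    Returns (CL/F in L/h, V/F in L, ka in 1/h).
    """
    t = np.asarray(times_h, float)
    c = np.asarray(conc_mg_l, float)
    c0 = max(c.max(), 1e-12)
    i_max = int(np.argmax(c))
    tmax = max(t[i_max], 0.25)
    ka0 = 2.0 / tmax
    ke0 = np.log(2.0) / max(t[-1] - tmax, 1.0)
    p0 = (c0 * 1.5, ka0, ke0)
    popt, _ = curve_fit(
        bateman, t, c, p0=p0, bounds=([1e-9, 1e-4, 1e-6], [np.inf, 100.0, 50.0]),
        maxfev=20000,
    )
    f_dose_v, ka, ke = popt
    if ka < ke:  # flip-flop ambiguity: report absorption as the faster process
        ka, ke = ke, ka
    v_over_f = dose_mg / f_dose_v
    cl_over_f = ke * v_over_f
    return float(cl_over_f), float(v_over_f), float(ka)


def simulate_noisy_profiles(
    drug: DrugParameters,
    dose_mg: float,
    n_profiles: int,
    seed: int,
    horizon_h: float = 48.0,
    noise_cv: float = 0.15,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Simulate one reference profile and overlay multiplicative lognormal
    residual noise per virtual profile (mg/L)."""
    scenario = Scenario(
        substrate=drug,
        substrate_regimen=Regimen.single(drug.name, dose_mg),
        horizon_h=horizon_h,
    )
    profile = simulate(scenario)[drug.name]
    keep = profile.times_h > 0
    t = profile.times_h[keep]
    c = profile.conc_ng_ml[keep] / 1000.0
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + noise_cv**2))
    out = []
    for _ in range(n_profiles):
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=c.shape)
        out.append((t, c * noise))
    return out
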