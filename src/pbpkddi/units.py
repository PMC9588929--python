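"""Centralized unit conversions.

Internal working units throughout the package are mg (mass), L (volume),
h (time) and mg/L (concentration).  Enzyme kinetic constants (Km, Ki) are
carried in µM and converted to mg/L with the compound's molecular weight at
the point of use.  In-vitro clearances arrive in the units they are reported
in (µL/min per mg microsomal protein, or µL/min per pmol enzyme) and are
scaled to whole-liver L/h here.
"""

from __future__ import annotations

import math

#: µL/min -> L/h
UL_PER_MIN_TO_L_PER_H = 60.0 / 1.0e6


def clint_hlm_to_whole_liver(
    clint_ul_min_mg: float, mppgl_mg_per_g: float, liver_weight_g: float
) -> float:
    """Scale a microsomal intrinsic clearance (µL/min/mg protein) to L/h for
    the whole liver."""
    return clint_ul_min_mg * mppgl_mg_per_g * liver_weight_g * UL_PER_MIN_TO_L_PER_H


def clint_rcyp_to_whole_liver(
    clint_ul_min_pmol: float,
    abundance_pmol_per_mg: float,
    mppgl_mg_per_g: float,
    liver_weight_g: float,
) -> float:
    """Scale a recombinant-enzyme intrinsic clearance (µL/min/pmol) to L/h
    for the whole liver via the hepatic enzyme abundance."""
    return (
        clint_ul_min_pmol
        * abundance_pmol_per_mg
        * mppgl_mg_per_g
        * liver_weight_g
        * UL_PER_MIN_TO_L_PER_H
    )


def vmax_rcyp_to_whole_liver_mg_h(
    vmax_pmol_min_pmol: float,
    abundance_pmol_per_mg: float,
    mppgl_mg_per_g: float,
    liver_weight_g: float,
    molecular_weight: float,
) -> float:
    """Scale a recombinant-enzyme Vmax (pmol/min/pmol enzyme) to mg/h for the
    whole liver."""
    pmol_per_min = (
        vmax_pmol_min_pmol * abundance_pmol_per_mg * mppgl_mg_per_g * liver_weight_g
    )
    # pmol/min -> mol/h -> g/h -> mg/h
    return pmol_per_min * 60.0 * 1.0e-12 * molecular_weight * 1.0e3


def um_to_mg_per_l(conc_um: float, molecular_weight: float) -> float:
    """µM -> mg/L."""
    return conc_um * molecular_weight / 1000.0


def mg_per_l_to_um(conc_mg_l: float, molecular_weight: float) -> float:
    """mg/L -> µM."""
    return conc_mg_l * 1000.0 / molecular_weight


def ka_from_peff(peff_cm_s: float, intestinal_radius_cm: float) -> float:
    """First-order absorption rate constant (1/h) from effective jejunal
    permeability, treating the small intestine as a cylinder: ka = 2*Peff/r."""
    return 2.0 * peff_cm_s * 3600.0 / intestinal_radius_cm


def papp_caco2_to_peff(papp_1e6_cm_s: float) -> float:
    """Convert an apparent Caco-2 permeability (in 10^-6 cm/s) to a human
    jejunal effective permeability (in 10^-4 cm/s).

    Uses the fixed log-log calibration line
    log10(Peff) = 0.4926 * log10(Papp) - 0.1454, a standard correlation
    between Caco-2 monolayer and human jejunal perfusion data.
    """
    if papp_1e6_cm_s <= 0:
        raise ValueError("Papp must be positive")
    return 10.0 ** (0.4926 * math.log10(papp_1e6_cm_s) - 0.1454)


def permeation_clearance_l_h(peff_cm_s: float, surface_area_cm2: float) -> float:
    """Permeability-limited clearance across the gut wall, CLperm = Peff * A,
    in L/h (cm^3/s -> L/h is a factor 3.6)."""
    return peff_cm_s * surface_area_cm2 * 3.6


def mg_l_to_ng_ml(conc_mg_l: float) -> float:
    """mg/L -> ng/mL (factor 1000)."""
    return conc_mg_l * 1000.0
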