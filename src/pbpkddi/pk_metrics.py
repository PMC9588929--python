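"""Non-compartmental PK summaries and the fold-error credibility metric.

AUC uses the log-linear trapezoidal rule: on a strictly decreasing positive
interval the log-down formula (C_i − C_{i+1}) / ln(C_i/C_{i+1}) · Δt applies;
otherwise the linear trapezoid (C_i + C_{i+1})/2 · Δt.  Any interval touching
zero falls back to the linear branch.  AUC∞ extrapolates beyond the last
sample with C_last/λz, where λz comes from a log-linear regression over the
terminal points (best adjusted-R² over the last 3–6 points after Tmax).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

AUCVariant = Literal["last", "inf", "tau", "0-24"]


def _check_profile(times: np.ndarray, conc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.ndim != 1 or times.shape != conc.shape:
        raise ValueError("times and concentrations must be 1-D and equal length")
    if times.size < 2:
        raise ValueError("need at least two profile points")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    return times, conc


def auc_trapezoid(times: np.ndarray, conc: np.ndarray) -> float:
    """Log-linear trapezoidal AUC over the full profile span."""
    times, conc = _check_profile(times, conc)
    dt = np.diff(times)
    c0, c1 = conc[:-1], conc[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_down = (c0 - c1) / np.log(c0 / c1) * dt
    linear = 0.5 * (c0 + c1) * dt
    use_log = (c0 > c1) & (c1 > 0)
    return float(np.sum(np.where(use_log, log_down, linear)))


def cmax_tmax(times: np.ndarray, conc: np.ndarray) -> tuple[float, float]:
    """Peak concentration and its earliest attaining time on the grid."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.size == 0:
        raise ValueError("empty profile")
    i = int(np.argmax(conc))  # argmax returns the first maximum: earliest tie
    return float(conc[i]), float(times[i])


def lambda_z(
    times: np.ndarray, conc: np.ndarray, min_points: int = 3, max_points: int = 6
) -> tuple[float, int, float]:
    """Terminal elimination rate constant (1/h) by log-linear regression.

    Candidate windows are the last 3–6 positive-concentration points strictly
    after Tmax; the window with the best adjusted R² wins.  Returns
    (λz, n points used, adjusted R²).
    """
    times, conc = _check_profile(times, conc)
    _, tmax = cmax_tmax(times, conc)
    mask = (times > tmax) & (conc > 0)
    t_sel, c_sel = times[mask], conc[mask]
    if t_sel.size < min_points:
        raise ValueError("need at least three positive terminal points after Tmax")
    best: Optional[tuple[float, float, int]] = None  # (adj R2, lz, n)
    logc = np.log(c_sel)
    for n in range(min_points, min(max_points, t_sel.size) + 1):
        tt, cc = t_sel[-n:], logc[-n:]
        slope, intercept = np.polyfit(tt, cc, 1)
        if slope >= 0:
            continue
        pred = slope * tt + intercept
        ss_res = float(np.sum((cc - pred) ** 2))
        ss_tot = float(np.sum((cc - cc.mean()) ** 2))
        if ss_tot == 0:
            r2 = 1.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or adj > best[0] + 1e-12:
            best = (adj, -slope, n)
    if best is None:
        raise ValueError("no negative terminal slope found")
    return float(best[1]), best[2], float(best[0])


def auc_inf(times: np.ndarray, conc: np.ndarray) -> float:
    """AUC extrapolated to infinity: AUC_last + C_last/λz."""
    times, conc = _check_profile(times, conc)
    if conc[-1] <= 0:
        raise ValueError("terminal concentration must be positive for AUC_inf")
    lz, _, _ = lambda_z(times, conc)
    return float(auc_trapezoid(times, conc) + conc[-1] / lz)


def auc_variant(times: np.ndarray, conc: np.ndarray, variant: AUCVariant) -> float:
    """Dispatch on the AUC variant tag used by the verification dataset."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if variant == "inf":
        return auc_inf(times, conc)
    if variant == "0-24":
        m = times <= 24.0 + 1e-9
        return auc_trapezoid(times[m], conc[m])
    return auc_trapezoid(times, conc)


def fold_error(observed: float, predicted: float) -> float:
    """Model-credibility fold error, max(obs/pred, pred/obs) ≥ 1."""
    if observed <= 0 or predicted <= 0:
        raise ValueError("fold error requires positive observed and predicted values")
    return max(observed / predicted, predicted / observed)


@dataclass(frozen=True)
class PKSummary:
    cmax_ng_ml: float
    tmax_h: float
    auc_ng_h_ml: float
    auc_variant: AUCVariant
    lambda_z_per_h: Optional[float] = None


def summarize(times: np.ndarray, conc: np.ndarray, variant: AUCVariant = "last") -> PKSummary:
    cmax, tmax = cmax_tmax(times, conc)
    lz = None
    if variant == "inf":
        lz, _, _ = lambda_z(times, conc)
    return PKSummary(
        cmax_ng_ml=cmax,
        tmax_h=tmax,
        auc_ng_h_ml=auc_variant(times, conc, variant),
        auc_variant=variant,
        lambda_z_per_h=lz,
    )


@dataclass(frozen=True)
class ValidationRecord:
    compound: str
    parameter: str
    observed: float
    predicted: float

    @property
    def fold_error(self) -> float:
        return fold_error(self.observed, self.predicted)

    def as_dict(self) -> dict:
        return {
            "compound": self.compound,
            "parameter": self.parameter,
            "observed": self.observed,
            "predicted": round(self.predicted, 4),
            "fold_error": round(self.fold_error, 4),
        }
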