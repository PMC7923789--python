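"""Mortality tabulation, LC50 estimation and toxicological unit conversions.

LC50 is estimated by least squares on the two-parameter log-logistic
(Hill) curve p(d) = 1 / (1 + (LC50/d)^slope), the standard
dose-response family with a closed-form LC50 parameter. When the fit
fails to converge, the estimate falls back to linear interpolation of %
mortality against log10(dose) between the doses bracketing 50%. Curves
that never reach 50% mortality yield an explicit censored outcome
("LC50 above the tested range"), never a number.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

METHOD_FIT = "loglogistic_fit"
METHOD_INTERP = "log_interpolation"

STATUS_OK = "ok"
STATUS_GT_MAX_DOSE = "gt_max_dose"


@dataclass
class MortalityCurve:
    """Per-dose (dead, total) counts for one treatment."""

    doses: np.ndarray
    dead: np.ndarray
    total: np.ndarray
    treatment_id: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.dead = np.asarray(self.dead, dtype=int)
        self.total = np.asarray(self.total, dtype=int)
        if not (len(self.doses) == len(self.dead) == len(self.total)):
            raise ValueError("doses, dead and total must share one length")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(self.dead < 0) or np.any(self.dead > self.total):
            raise ValueError("need 0 <= dead <= total at every dose")


class LC50Estimate(NamedTuple):
    lc50: float
    hill_slope: float
    method: str
    converged: bool
    status: str


def mortality_percent(curve: MortalityCurve) -> np.ndarray:
    """Per-dose % mortality, 100 * dead / total."""
    if np.any(curve.total == 0):
        raise ValueError("every dose needs total > 0")
    return 100.0 * curve.dead / curve.total


def loglogistic(dose, lc50, hill_slope):
    """Hill mortality curve; p(0) = 0 and p(lc50) = 0.5."""
    dose = np.asarray(dose, dtype=float)
    # work in log space to avoid overflow at extreme dose/LC50 ratios
    log_ratio = np.where(dose > 0, np.log(lc50) - np.log(np.maximum(dose, 1e-300)), 0.0)
    p = 1.0 / (1.0 + np.exp(np.clip(hill_slope * log_ratio, -700.0, 700.0)))
    return np.where(dose > 0, p, 0.0)


def interpolate_lc50(curve: MortalityCurve) -> float:
    """LC50 by linear interpolation of % mortality against log10(dose).

    Uses the first pair of positive doses bracketing 50% mortality.
    """
    pct = mortality_percent(curve)
    pos = curve.doses > 0
    doses = curve.doses[pos]
    pct = pct[pos]
    if len(doses) < 2:
        raise ValueError("need at least two positive doses to interpolate")
    for i in range(len(doses) - 1):
        lo, hi = pct[i], pct[i + 1]
        if lo <= 50.0 <= hi and hi > lo:
            f = (50.0 - lo) / (hi - lo)
            return float(10 ** (np.log10(doses[i]) + f * (np.log10(doses[i + 1]) - np.log10(doses[i]))))
        if lo == hi == 50.0:
            return float(10 ** ((np.log10(doses[i]) + np.log10(doses[i + 1])) / 2.0))
    raise ValueError("mortality does not bracket 50% on the tested doses")


def fit_lc50(
    curve: MortalityCurve, method: str = "auto", weighted: bool = False
) -> LC50Estimate:
    """Estimate LC50 from a mortality curve.

    method: "auto" (fit, interpolation fallback), "fit", or "interpolation".
    ``weighted`` applies binomial sigma = sqrt(p(1-p)/n) weights to the fit.
    Returns a censored gt_max_dose outcome when mortality never reaches 50%.
    """
    if len(curve.doses) < 2:
        raise ValueError("need at least 2 dose levels")
    pct = mortality_percent(curve)
    if pct.max() < 50.0:
        return LC50Estimate(np.nan, np.nan, method, False, STATUS_GT_MAX_DOSE)

    if method == "interpolation":
        lc50 = interpolate_lc50(curve)
        return LC50Estimate(lc50, np.nan, METHOD_INTERP, True, STATUS_OK)
    if method not in ("auto", "fit"):
        raise ValueError("method must be 'auto', 'fit' or 'interpolation'")

    props = pct / 100.0
    try:
        guess = interpolate_lc50(curve)
    except ValueError:
        guess = float(np.exp(np.mean(np.log(curve.doses[curve.doses > 0]))))
    sigma = None
    if weighted:
        p = np.clip(props, 0.02, 0.98)
        sigma = np.sqrt(p * (1.0 - p) / curve.total)
    try:
        # Fit (log LC50, slope): shift-equivariant in log dose, so the
        # estimate is scale-equivariant in dose.
        popt, _ = curve_fit(
            lambda d, log_lc50, slope: loglogistic(d, np.exp(log_lc50), slope),
            curve.doses,
            props,
            p0=[np.log(guess), 2.0],
            sigma=sigma,
            bounds=([np.log(guess) - 12.0, 0.05], [np.log(guess) + 12.0, 60.0]),
            maxfev=20000,
        )
        lc50, slope = float(np.exp(popt[0])), float(popt[1])
        return LC50Estimate(lc50, slope, METHOD_FIT, True, STATUS_OK)
    except (RuntimeError, ValueError):
        if method == "fit":
            return LC50Estimate(np.nan, np.nan, METHOD_FIT, False, STATUS_OK)
        lc50 = interpolate_lc50(curve)
        return LC50Estimate(lc50, np.nan, METHOD_INTERP, True, STATUS_OK)


def mass_in_well(concentration_mg_L: float, volume_L: float) -> float:
    """Total compound mass (mg) in a well: concentration (mg/L) x volume (L)."""
    if concentration_mg_L < 0 or volume_L < 0:
        raise ValueError("concentration and volume must be >= 0")
    return concentration_mg_L * volume_L


def dose_for_body(dose_per_bw_mg_kg: float, body_weight_kg: float) -> float:
    """Absolute dose (mg) for an animal: mg/kg bw x body weight (kg)."""
    if body_weight_kg <= 0:
        raise ValueError("body weight must be > 0")
    return dose_per_bw_mg_kg * body_weight_kg


class AdiResult(NamedTuple):
    raw: float
    rounded: float


def adi_from_noael(noael_mg_kg_day: float, uncertainty_factor: float) -> AdiResult:
    """Acceptable daily intake: NOAEL / uncertainty factor (raw and 2-dp rounded)."""
    if uncertainty_factor < 1:
        raise ValueError("uncertainty factor must be >= 1")
    raw = noael_mg_kg_day / uncertainty_factor
    return AdiResult(raw=raw, rounded=round(raw, 2))
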