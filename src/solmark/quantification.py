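"""Calibration-curve quantification, LLOQ censoring, and metabolic ratios.

Solanidine is quantified in ng/mL against a linear calibration fitted by
weighted least squares with 1/concentration weights (the standard LC-MS/MS
convention for heteroscedastic response).  The five monitored metabolite
ions (m/z 414, 416, 444, 430, 412) have no authentic reference standards,
so they are carried as semi-quantitative responses (peak area / internal
standard area) and never converted to concentrations.

Censoring rules:

* a subject whose parent solanidine concentration falls below the LLOQ
  (0.01 ng/mL) is excluded from analysis;
* a metabolite response below its per-ion LLOQ (defined operationally at
  signal-to-noise 10) is imputed at half the LLOQ and flagged; zero or
  negative responses count as below-LLOQ.

Metabolic ratios — metabolite response divided by solanidine concentration —
are the CYP2D6 activity readout and are defined only for retained subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "METABOLITE_IONS",
    "SOLANIDINE_LLOQ",
    "CalibrationError",
    "CalibrationCurve",
    "CensoringRules",
    "fit_calibration",
    "quantify",
    "apply_censoring",
    "retained",
    "compute_ratios",
]

METABOLITE_IONS = ("mz414", "mz416", "mz444", "mz430", "mz412")
SOLANIDINE_LLOQ = 0.01  # ng/mL


class CalibrationError(ValueError):
    """Invalid calibration inputs or an unusable fitted curve."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration: response = slope * concentration + intercept."""

    slope: float
    intercept: float
    weighting: str = "1/x"
    r: float = float("nan")
    n_standards: int = 0

    def predict(self, concentration):
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept

    def invert(self, response):
        return (np.asarray(response, dtype=float) - self.intercept) / self.slope


def fit_calibration(
    concentrations: Iterable[float],
    responses: Iterable[float],
    weighting: str = "1/x",
) -> CalibrationCurve:
    """Fit a weighted (1/x) or unweighted linear calibration curve.

    Requires at least three distinct, strictly positive standard
    concentrations.  ``r`` is the (weighted) correlation of the fit.
    """
    c = np.asarray(list(concentrations), dtype=float)
    y = np.asarray(list(responses), dtype=float)
    if c.shape != y.shape:
        raise CalibrationError("concentration and response lengths differ")
    if c.size < 3 or np.unique(c).size < 3:
        raise CalibrationError("need >= 3 standards with distinct concentrations")
    if np.any(c <= 0):
        raise CalibrationError("standard concentrations must be > 0")
    if weighting not in ("1/x", "none"):
        raise CalibrationError(f"unknown weighting {weighting!r}")
    w = 1.0 / c if weighting == "1/x" else np.ones_like(c)
    res = sm.WLS(y, sm.add_constant(c), weights=w).fit()
    slope = float(res.params[1])
    intercept = float(res.params[0])
    if slope <= 0:
        raise CalibrationError(f"calibration slope must be > 0, got {slope}")
    r = float(np.sqrt(max(res.rsquared, 0.0)))
    return CalibrationCurve(slope, intercept, weighting, r, n_standards=int(c.size))


def quantify(responses, curve: CalibrationCurve):
    """Invert a calibration curve: concentration = (response - intercept)/slope.

    Returns ``(concentration, quantifiable)`` where concentrations <= 0 are
    flagged non-quantifiable (mask False).  Scalar input gives scalar output.
    """
    scalar = np.isscalar(responses)
    conc = curve.invert(np.atleast_1d(responses))
    ok = conc > 0
    if scalar:
        return float(conc[0]), bool(ok[0])
    return conc, ok


@dataclass(frozen=True)
class CensoringRules:
    """Parent-exclusion and metabolite half-LLOQ imputation thresholds."""

    solanidine_lloq: float = SOLANIDINE_LLOQ
    metabolite_lloq: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.solanidine_lloq <= 0:
            raise ValueError("solanidine LLOQ must be > 0")
        for ion, lloq in self.metabolite_lloq.items():
            if lloq <= 0:
                raise ValueError(f"metabolite LLOQ for {ion} must be > 0")


def apply_censoring(panel: pd.DataFrame, rules: CensoringRules) -> pd.DataFrame:
    """Apply LLOQ censoring to a biomarker panel table.

    Adds an ``excluded`` column (parent solanidine below LLOQ or missing),
    and for each metabolite ion with a configured LLOQ a ``censored_<ion>``
    flag with below-LLOQ responses replaced by half the LLOQ.  The operation
    is idempotent: re-applying it changes nothing.
    """
    if "solanidine" not in panel.columns:
        raise KeyError("panel lacks a 'solanidine' column")
    out = panel.copy()
    sol = out["solanidine"].astype(float)
    out["excluded"] = sol.isna() | (sol < rules.solanidine_lloq)
    for ion, lloq in rules.metabolite_lloq.items():
        if ion not in out.columns:
            continue
        vals = out[ion].astype(float)
        below = vals.isna() | (vals <= 0) | (vals < lloq)
        out[ion] = vals.where(~below, lloq / 2.0)
        flag_col = f"censored_{ion}"
        prior = out[flag_col] if flag_col in out.columns else False
        out[flag_col] = below | prior
    return out


def retained(panel: pd.DataFrame) -> pd.DataFrame:
    """Rows surviving parent-LLOQ exclusion (requires apply_censoring first)."""
    if "excluded" not in panel.columns:
        raise KeyError("panel has no 'excluded' column; run apply_censoring first")
    return panel.loc[~panel["excluded"]]


def compute_ratios(
    panel: pd.DataFrame, ions: Iterable[str] = METABOLITE_IONS
) -> pd.DataFrame:
    """Append ``ratio_<ion>`` = metabolite response / solanidine concentration.

    Excluded subjects must be removed beforehand: ratios are undefined when
    the parent is below LLOQ, so their presence is a contract violation.
    """
    if "excluded" in panel.columns and bool(panel["excluded"].any()):
        raise ValueError("panel contains excluded subjects; drop them before computing ratios")
    out = panel.copy()
    sol = out["solanidine"].astype(float)
    if (sol <= 0).any() or sol.isna().any():
        raise ValueError("non-positive or missing solanidine concentration in retained panel")
    for ion in ions:
        if ion in out.columns:
            out[f"ratio_{ion}"] = out[ion].astype(float) / sol
    return out
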