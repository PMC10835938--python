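"""In vitro solanidine clearance: depletion kinetics, scaling, inhibition, fm.

Substrate-depletion incubations (human liver microsomes or recombinant
CYP2D6) follow first-order decay, C(t) = C0 * exp(-k t); the rate constant
is the negative slope of an ordinary least-squares fit of ln(concentration)
against time.  From k:

* half-life      t1/2 = ln(2) / k                       [min]
* intrinsic CL   CLint = k / protein concentration      [mL/min/mg]
* whole-liver CL CLint,liver = CLint * MPPGL * liver mass, converted to L/h
* hepatic CL     well-stirred model, CLh = Q fu CLint,liver / (Q + fu CLint,liver),
                 bounded above by hepatic blood flow Q.

Inhibition is the percent reduction of CLint versus control.  The cohort-
level fraction metabolized by CYP2D6 is estimated from the gPM/gNM
geometric-mean concentrations under the assumption that concentration
differences between phenotypes reflect inverse clearance differences:
fm = 1 - GM_gNM / GM_gPM.

Scaling constants default to textbook values (MPPGL 40 mg/g, liver 1800 g,
Q 90 L/h, fu 1) and are fully configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "KineticResult",
    "ScalingConstants",
    "fit_depletion",
    "clint",
    "scale_hepatic",
    "percent_inhibition",
    "fraction_metabolized",
]


@dataclass(frozen=True)
class KineticResult:
    """First-order depletion fit: rate constant, half-life, fit R^2."""

    k: float            # 1/min
    half_life: float    # min (inf when k == 0)
    r_squared: float


@dataclass(frozen=True)
class ScalingConstants:
    """Physiological constants for scaling microsomal CLint to hepatic CL."""

    mppgl: float = 40.0             # mg microsomal protein / g liver
    liver_mass_g: float = 1800.0
    hepatic_blood_flow_l_h: float = 90.0
    fu: float = 1.0                 # unbound fraction in blood

    def __post_init__(self) -> None:
        if min(self.mppgl, self.liver_mass_g, self.hepatic_blood_flow_l_h, self.fu) <= 0:
            raise ValueError("all scaling constants must be > 0")
        if self.fu > 1:
            raise ValueError("fu must be <= 1")


def fit_depletion(time_min: Sequence[float], concentration: Sequence[float]) -> KineticResult:
    """Fit ln(concentration) vs time by OLS; k is the negative slope.

    Requires >= 3 time points including t = 0 region coverage and strictly
    positive concentrations.  An increasing profile yields k clipped at 0
    with a warning (no negative rates).
    """
    t = np.asarray(list(time_min), dtype=float)
    c = np.asarray(list(concentration), dtype=float)
    if t.size != c.size:
        raise ValueError("time and concentration lengths differ")
    if t.size < 2:
        raise ValueError("need at least two time points")
    if np.any(c <= 0) or np.any(~np.isfinite(c)):
        raise ValueError("concentrations must be finite and > 0 for log fitting")
    logc = np.log(c)
    slope, intercept = np.polyfit(t, logc, 1)
    pred = slope * t + intercept
    ss_tot = np.sum((logc - logc.mean()) ** 2)
    r2 = 1.0 - np.sum((logc - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    k = -float(slope)
    if k < 0:
        warnings.warn("increasing depletion profile; rate constant clipped at 0")
        k = 0.0
    half_life = float(np.log(2) / k) if k > 0 else float("inf")
    return KineticResult(k=k, half_life=half_life, r_squared=float(r2))


def clint(k: float, protein_mg_ml: float) -> float:
    """Intrinsic clearance: depletion rate / protein concentration [mL/min/mg]."""
    if protein_mg_ml <= 0:
        raise ValueError("protein concentration must be > 0")
    if k < 0:
        raise ValueError("rate constant must be >= 0")
    return k / protein_mg_ml


def scale_hepatic(
    clint_ml_min_mg: float, constants: ScalingConstants | None = None
) -> tuple[float, float]:
    """Well-stirred hepatic clearance from microsomal CLint.

    Returns ``(CLh in L/h, percent of hepatic blood flow)``.
    """
    c = constants or ScalingConstants()
    if clint_ml_min_mg < 0:
        raise ValueError("CLint must be >= 0")
    clint_liver_l_h = clint_ml_min_mg * c.mppgl * c.liver_mass_g * 60.0 / 1000.0
    q = c.hepatic_blood_flow_l_h
    cl_h = q * c.fu * clint_liver_l_h / (q + c.fu * clint_liver_l_h) if clint_liver_l_h > 0 else 0.0
    return float(cl_h), float(100.0 * cl_h / q)


def percent_inhibition(control_clint: float, inhibited_clint: float) -> float:
    """Percent reduction of CLint by an inhibitor: (1 - inhibited/control) * 100."""
    if control_clint <= 0:
        raise ValueError("control CLint must be > 0")
    if inhibited_clint < 0:
        raise ValueError("inhibited CLint must be >= 0")
    return (1.0 - inhibited_clint / control_clint) * 100.0


def fraction_metabolized(gm_pm: float, gm_nm: float) -> float:
    """Enzyme-mediated clearance fraction from phenotype geometric means.

    Assuming steady-state concentrations scale inversely with clearance,
    losing the enzyme entirely (gPM) raises concentration by CL_nm/CL_residual,
    so fm = 1 - GM_nm / GM_pm.  A non-positive result (gPM mean not above the
    gNM mean) is returned with a warning rather than raised.
    """
    if gm_pm <= 0 or gm_nm <= 0:
        raise ValueError("geometric means must be > 0")
    fm = 1.0 - gm_nm / gm_pm
    if fm <= 0:
        warnings.warn("gPM mean does not exceed gNM mean; fm estimate is not meaningful")
    return fm
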