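"""Synthetic cohort, genotype-panel, and depletion-curve generators.

No subject-level data accompany the published solanidine cohort, so every
analysis stage here is exercised on synthetic cohorts whose statistical
structure matches the published summary tables:

* four phenotype groups (default sizes 9/89/196/20 for gPM/gIM/gNM/gUM);
* per-group lognormal distributions for solanidine and each metabolite-to-
  solanidine ratio, with geometric means taken from the published group
  means and log-scale SDs backed out of the printed 95% CIs
  (sigma = sqrt(n) * ln(ci_high/ci_low) / (2 z), z = 1.96 — a normal
  quantile, since these are calibration heuristics rather than estimates);
* metabolite responses derived as ratio x solanidine, then censored exactly
  as the quantification rules dictate (parent-LLOQ exclusion, half-LLOQ
  metabolite imputation).  Default per-ion response LLOQs are solved so the
  phenotype-mixture below-LLOQ fractions reproduce the published
  detected-subject counts;
* star-allele diplotypes drawn from an illustrative per-class table that is
  consistent with the activity-score bins (so annotating the truth table
  reproduces the phenotype labels);
* a SNP dosage panel in which the causal variant's dosage is the subject's
  no-function allele count, LD proxies are degraded copies of the causal
  dosage hitting target r^2 values, and background variants are independent.

The generator retains the pre-censoring truth next to the censored observed
table so recovery tests can compare estimates against the generating
parameters.  Every stochastic entry point takes a mandatory seed and is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from . import reference
from .genotype_phenotype import DEFAULT_ALLELE_FUNCTION, parse_diplotype
from .gwas import DosageMatrix, ld_r2
from .quantification import (
    METABOLITE_IONS,
    CensoringRules,
    apply_censoring,
    compute_ratios,
    retained,
)

__all__ = [
    "backout_log_sd",
    "default_endpoint_params",
    "default_metabolite_lloqs",
    "CohortConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "DosagePanelConfig",
    "simulate_dosages",
    "simulate_depletion",
]

_Z975 = 1.959963984540054


def backout_log_sd(n: int, ci_low: float, ci_high: float, z: float = _Z975) -> float:
    """Log-scale SD implied by a geometric-mean 95% CI.

    Inverts GM * exp(+/- z * sigma / sqrt(n)):
    sigma = sqrt(n) * ln(ci_high / ci_low) / (2 z).
    """
    if n < 2:
        raise ValueError("need n >= 2 to back out a dispersion")
    if ci_low <= 0 or ci_high < ci_low:
        raise ValueError("CI bounds must satisfy 0 < ci_low <= ci_high")
    return math.sqrt(n) * math.log(ci_high / ci_low) / (2.0 * z)


def default_endpoint_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-endpoint, per-group (geometric mean, log SD) calibration defaults."""
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for endpoint, groups in reference.GEOMETRIC_MEANS.items():
        out[endpoint] = {}
        for cls, (gm, lo, hi) in groups.items():
            n = reference.GROUP_SIZES[cls]
            out[endpoint][cls] = (gm, backout_log_sd(n, lo, hi))
    return out


def _response_params(endpoint_params, cls):
    """Log-mean/SD of a metabolite *response* (= ratio x solanidine) per class."""
    gm_s, sd_s = endpoint_params["solanidine"][cls]
    out = {}
    for endpoint, groups in endpoint_params.items():
        if endpoint == "solanidine":
            continue
        gm_r, sd_r = groups[cls]
        mu = math.log(gm_r) + math.log(gm_s)
        sd = math.hypot(sd_r, sd_s)  # ratio and parent drawn independently
        out[endpoint.replace("ratio_", "")] = (mu, sd)
    return out


def default_metabolite_lloqs(
    endpoint_params: Mapping | None = None,
    group_sizes: Mapping[str, int] | None = None,
    detected: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Per-ion response LLOQs matching the published below-LLOQ fractions.

    Solves, per ion, for the response level at which the phenotype-mixture
    lognormal model leaves the published fraction of retained subjects below
    the limit (e.g. 89/314 for m/z 412).
    """
    params = endpoint_params or default_endpoint_params()
    sizes = dict(group_sizes or reference.GROUP_SIZES)
    det = dict(detected or reference.METABOLITE_DETECTED)
    total = sum(sizes.values())
    weights = {c: n / total for c, n in sizes.items()}
    by_class = {c: _response_params(params, c) for c in sizes}
    out: dict[str, float] = {}
    for ion, n_det in det.items():
        target = (total - n_det) / total

        def below_frac(log_l: float) -> float:
            acc = 0.0
            for c, w in weights.items():
                mu, sd = by_class[c][ion]
                if sd == 0:  # degenerate group: point mass at mu
                    acc += w * float(log_l > mu)
                else:
                    acc += w * norm.cdf((log_l - mu) / sd)
            return acc - target

        log_l = brentq(below_frac, -60.0, 60.0)
        out[ion] = float(math.exp(log_l))
    return out


#: Illustrative diplotypes per phenotype class (consistent with the AS bins,
#: not a claim about the real cohort's genotype distribution).
DEFAULT_DIPLOTYPE_OPTIONS: dict[str, tuple[str, ...]] = {
    "gPM": ("*4/*4", "*4/*6", "*3/*4", "*4/*5"),
    "gIM": ("*1/*4", "*4/*41", "*41/*41", "*1/*5", "*10/*41"),
    "gNM": ("*1/*1", "*1/*2", "*1/*41", "*2/*2"),
    "gUM": ("*1x2/*1", "*1x2/*2", "*2x2/*1"),
}


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort generator."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(reference.GROUP_SIZES)
    )
    endpoint_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=default_endpoint_params
    )
    solanidine_lloq: float = reference.SOLANIDINE_LLOQ_NG_ML
    metabolite_lloqs: dict[str, float] | None = None  # None -> solved defaults
    sex_p_female: float = 0.5
    period_p: float = 0.5
    nfib_carrier_p: float = reference.NFIB_CARRIERS_GNM / reference.GROUP_SIZES["gNM"]
    bodyweight_mean_kg: float = reference.MEAN_BODYWEIGHT_KG
    bodyweight_sd_kg: float = reference.SD_BODYWEIGHT_KG
    log_corr: float = 0.0  # within-subject log-scale corr(solanidine, each ratio)
    diplotype_options: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DIPLOTYPE_OPTIONS)
    )

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        for endpoint, groups in self.endpoint_params.items():
            for cls, (gm, sd) in groups.items():
                if gm <= 0 or sd < 0:
                    raise ValueError(f"invalid calibration for {endpoint}/{cls}")
        if not -1.0 <= self.log_corr <= 1.0:
            raise ValueError("log_corr must lie in [-1, 1]")
        for cls, n in self.group_sizes.items():
            if n > 0 and not self.diplotype_options.get(cls):
                raise ValueError(f"no diplotype option configured for class {cls}")


@dataclass
class SyntheticCohort:
    """Generated cohort: pre-censoring truth plus censored observed table."""

    truth: pd.DataFrame
    observed: pd.DataFrame
    config: CohortConfig
    seed: int

    @property
    def retained(self) -> pd.DataFrame:
        return retained(self.observed)


def _lognormal_weight_params(mean: float, sd: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) matching an arithmetic mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma = math.sqrt(math.log1p(cv2))
    mu = math.log(mean) - sigma**2 / 2.0
    return mu, sigma


def simulate_cohort(cfg: CohortConfig | None, seed: int) -> SyntheticCohort:
    """Draw a phenotype-stratified cohort with biomarker panel and covariates.

    Per subject: phenotype-conditional lognormal solanidine and metabolite
    ratios (optionally log-correlated via ``cfg.log_corr``), responses as
    ratio x solanidine, a class-consistent diplotype, NFIB carrier status and
    demographics.  Censoring is then applied exactly as in the
    quantification pipeline; the pre-censoring truth is kept alongside.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(seed)
    ratio_endpoints = [e for e in cfg.endpoint_params if e != "solanidine"]
    rho = cfg.log_corr
    mu_bw, sd_bw = _lognormal_weight_params(cfg.bodyweight_mean_kg, cfg.bodyweight_sd_kg)

    records: list[dict] = []
    sid = 0
    for cls in reference.PHENOTYPES:
        n = cfg.group_sizes.get(cls, 0)
        if n == 0:
            continue
        gm_s, sd_s = cfg.endpoint_params["solanidine"][cls]
        z0 = rng.standard_normal(n)
        sol = gm_s * np.exp(sd_s * z0)
        ratios = {}
        for endpoint in ratio_endpoints:
            gm_r, sd_r = cfg.endpoint_params[endpoint][cls]
            zi = rho * z0 + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
            ratios[endpoint] = gm_r * np.exp(sd_r * zi)
        dips = rng.choice(cfg.diplotype_options[cls], size=n)
        sex = rng.random(n) < cfg.sex_p_female
        period = rng.random(n) < cfg.period_p
        nfib = rng.random(n) < cfg.nfib_carrier_p
        bw = np.exp(mu_bw + sd_bw * rng.standard_normal(n))
        for i in range(n):
            sid += 1
            rec = {
                "subject_id": f"S{sid:04d}",
                "phenotype": cls,
                "diplotype": str(dips[i]),
                "nfib_carrier": bool(nfib[i]),
                "sex_female": int(sex[i]),
                "bodyweight_kg": float(bw[i]),
                "period": int(period[i]),
                "solanidine": float(sol[i]),
            }
            for endpoint in ratio_endpoints:
                ion = endpoint.replace("ratio_", "")
                rec[ion] = float(ratios[endpoint][i] * sol[i])
                rec[endpoint] = float(ratios[endpoint][i])
            records.append(rec)
    truth = pd.DataFrame.from_records(records)

    lloqs = cfg.metabolite_lloqs
    if lloqs is None:
        lloqs = default_metabolite_lloqs(cfg.endpoint_params, cfg.group_sizes)
    rules = CensoringRules(solanidine_lloq=cfg.solanidine_lloq, metabolite_lloq=lloqs)
    meas_cols = ["subject_id", "phenotype", "diplotype", "nfib_carrier",
                 "sex_female", "bodyweight_kg", "period", "solanidine",
                 *[e.replace("ratio_", "") for e in ratio_endpoints]]
    observed = apply_censoring(truth[meas_cols], rules)
    kept = compute_ratios(retained(observed))
    observed = observed.merge(
        kept[["subject_id", *[f"ratio_{e.replace('ratio_', '')}" for e in ratio_endpoints]]],
        on="subject_id", how="left",
    )
    return SyntheticCohort(truth=truth, observed=observed, config=cfg, seed=seed)


@dataclass
class DosagePanelConfig:
    """SNP panel layout: one causal variant, LD proxies, independent background."""

    n_background: int = 500
    proxy_r2: tuple[float, ...] = (0.9, 0.8, 0.6)
    r2_tol: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_id: str = "causal_nofun"
    max_tries: int = 200

    def __post_init__(self) -> None:
        if any(not 0.0 < t <= 1.0 for t in self.proxy_r2):
            raise ValueError("proxy r^2 targets must lie in (0, 1]")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")


def _no_function_dosage(diplotypes: Sequence[str], allele_table=None) -> np.ndarray:
    tab = allele_table or DEFAULT_ALLELE_FUNCTION
    out = []
    for text in diplotypes:
        d = parse_diplotype(str(text))
        count = sum(h.copy_number for h in d.haplotypes if tab[h.allele] == 0.0)
        out.append(min(count, 2))
    return np.asarray(out, dtype=float)


def simulate_dosages(
    diplotypes: Sequence[str],
    cfg: DosagePanelConfig | None,
    seed: int,
    allele_table=None,
) -> DosageMatrix:
    """Build a dosage panel around a cohort's no-function allele counts.

    The causal variant is deterministic (no-function allele count per
    subject, capped at 2).  Each proxy starts as a copy of the causal dosage
    with a fraction of entries replaced by independent draws, retried until
    the achieved r^2 lies within ``r2_tol`` of its target.  Background
    variants are binomial(2, maf) with maf uniform over ``maf_range``.
    """
    cfg = cfg or DosagePanelConfig()
    rng = np.random.default_rng(seed)
    causal = _no_function_dosage(diplotypes, allele_table)
    if causal.std() == 0:
        raise ValueError("causal no-function dosage is monomorphic in this cohort")
    n = causal.size
    p_hat = causal.mean() / 2.0
    cols = [causal]
    ids = [cfg.causal_id]
    chroms = ["22"]
    poss = [42130000]
    for j, target in enumerate(cfg.proxy_r2):
        if target == 1.0:
            prox = causal.copy()
        else:
            frac = 1.0 - math.sqrt(target)
            prox = None
            for attempt in range(cfg.max_tries):
                mask = rng.random(n) < frac
                cand = causal.copy()
                cand[mask] = rng.binomial(2, p_hat, size=int(mask.sum()))
                if cand.std() == 0:
                    continue
                achieved = ld_r2(causal, cand)
                if abs(achieved - target) <= cfg.r2_tol:
                    prox = cand
                    break
                # nudge the replacement fraction toward the target
                if achieved > target:
                    frac = min(1.0, frac * 1.1 + 0.01)
                else:
                    frac = max(0.0, frac * 0.9 - 0.01)
            if prox is None:
                raise ValueError(f"could not achieve proxy r^2 target {target}")
        cols.append(prox)
        ids.append(f"proxy_r2_{target:g}")
        chroms.append("22")
        poss.append(42131000 + 1000 * j)
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_background)
    for j in range(cfg.n_background):
        cols.append(rng.binomial(2, mafs[j], size=n).astype(float))
        ids.append(f"bg_{j:05d}")
        chroms.append(str(1 + (j % 21)))
        poss.append(1_000_000 + 1_000 * j)
    meta = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return DosageMatrix(np.column_stack(cols), meta)


def simulate_depletion(
    k: float,
    times_min: Sequence[float],
    seed: int,
    c0: float = 100.0,
    cv: float = 0.0,
) -> pd.DataFrame:
    """First-order depletion curve with multiplicative lognormal noise.

    C(t) = c0 * exp(-k t) * eps, with eps mean-1 lognormal at the given CV
    (cv = 0 gives the exact exponential).  Times must include 0.
    """
    t = np.asarray(list(times_min), dtype=float)
    if k < 0:
        raise ValueError("rate constant must be >= 0")
    if cv < 0:
        raise ValueError("noise CV must be >= 0")
    if not np.any(t == 0):
        raise ValueError("time grid must include t = 0")
    rng = np.random.default_rng(seed)
    conc = c0 * np.exp(-k * t)
    if cv > 0:
        sigma = math.sqrt(math.log1p(cv**2))
        conc = conc * np.exp(rng.standard_normal(t.size) * sigma - sigma**2 / 2.0)
    return pd.DataFrame({"time_min": t, "concentration": conc})
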