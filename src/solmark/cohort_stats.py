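"""Log-scale group contrasts for biomarker endpoints.

Biomarker endpoints (solanidine concentration and the metabolite-to-
solanidine ratios) are right-skewed and analysed on the natural-log scale
throughout; printed values are back-transformed, so group location is a
geometric mean and a between-group contrast is a geometric-mean ratio.

The workflow mirrors standard pharmacogenetic cohort analysis:

1. per-class geometric means with t-based 95% CIs;
2. forward-stepwise selection of demographic covariates (entry p <= 0.05,
   removal p >= 0.10) on the log endpoint;
3. one-way ANOVA of the log endpoint on phenotype class, adjusted for the
   selected covariates, with Fisher's-LSD pairwise contrasts against the
   normal-metabolizer reference (unadjusted p-values from the pooled
   residual variance — that is what LSD means; no multiplicity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .genotype_phenotype import PHENOTYPE_CODES

__all__ = [
    "GroupSummary",
    "ContrastResult",
    "geometric_mean_ci",
    "group_summaries",
    "pooled_geometric_mean",
    "percent_change",
    "format_percent_change",
    "stepwise_covariates",
    "anova_lsd_contrasts",
    "table1_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """Geometric mean with a 95% CI from a t-interval on the log scale."""

    n: int
    gm: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ContrastResult:
    """Geometric-mean ratio versus the reference class (Fisher's LSD)."""

    ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    log_diff: float
    se: float
    df: float


def geometric_mean_ci(values: Iterable[float], level: float = 0.95) -> GroupSummary:
    """Geometric mean and CI: exp(mean log +/- t_{1-a/2, n-1} * SE of log)."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("values must be finite and > 0 for a geometric mean")
    logs = np.log(x)
    m = logs.mean()
    if x.size == 1:
        return GroupSummary(1, float(np.exp(m)), float("nan"), float("nan"))
    se = logs.std(ddof=1) / np.sqrt(x.size)
    tcrit = st.t.ppf(0.5 + level / 2.0, x.size - 1)
    return GroupSummary(
        int(x.size),
        float(np.exp(m)),
        float(np.exp(m - tcrit * se)),
        float(np.exp(m + tcrit * se)),
    )


def group_summaries(
    values: Sequence[float], phenotypes: Sequence[str], level: float = 0.95
) -> dict[str, GroupSummary]:
    """Per-class geometric-mean summaries, ordered gPM -> gUM."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "cls": list(phenotypes)})
    order = sorted(df["cls"].unique(), key=lambda c: PHENOTYPE_CODES.get(c, 99))
    return {c: geometric_mean_ci(df.loc[df["cls"] == c, "value"], level) for c in order}


def pooled_geometric_mean(groups: Iterable[GroupSummary]) -> float:
    """Size-weighted pooled GM: exp(sum n_g ln GM_g / sum n_g)."""
    gs = list(groups)
    if not gs:
        raise ValueError("no groups supplied")
    n = np.array([g.n for g in gs], dtype=float)
    lg = np.array([np.log(g.gm) for g in gs])
    if np.any(n < 1) or np.any(~np.isfinite(lg)):
        raise ValueError("each group needs n >= 1 and GM > 0")
    return float(np.exp(np.sum(n * lg) / np.sum(n)))


def percent_change(ratio: float) -> float:
    """Signed percent change implied by a GM ratio: (ratio - 1) * 100."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    return (ratio - 1.0) * 100.0


def format_percent_change(ratio: float, ndigits: int = 1) -> str:
    """Render a ratio the way cohort reports read, e.g. 0.653 -> '34.7% lower'."""
    pc = percent_change(ratio)
    if pc < 0:
        return f"{-pc:.{ndigits}f}% lower"
    if pc > 0:
        return f"{pc:.{ndigits}f}% higher"
    return "0% change"


def _ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, X).fit()


def stepwise_covariates(
    log_values: Sequence[float],
    candidates: pd.DataFrame,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_iter: int = 50,
) -> list[str]:
    """Forward-stepwise covariate selection with backward removal.

    Candidates enter one at a time at the smallest partial-F p-value if it is
    <= ``entry_p`` (for a single added column the partial F equals the squared
    t of its coefficient), then any included covariate with p >= ``removal_p``
    is dropped; the cycle repeats to convergence.  Constant candidates are
    skipped with a warning; a candidate collinear with the current model
    cannot enter.
    """
    y = np.asarray(log_values, dtype=float)
    n = y.size
    if n <= candidates.shape[1] + 2:
        raise ValueError("too few observations for stepwise selection")
    usable: list[str] = []
    for name in candidates.columns:
        col = np.asarray(candidates[name], dtype=float)
        if np.std(col) == 0 or not np.all(np.isfinite(col)):
            warnings.warn(f"candidate {name!r} is constant or non-finite; skipped")
            continue
        usable.append(name)

    def design(names: list[str]) -> np.ndarray:
        cols = [np.ones(n)] + [np.asarray(candidates[c], dtype=float) for c in names]
        return np.column_stack(cols)

    selected: list[str] = []
    for _ in range(max_iter):
        changed = False
        # forward entry
        best_name, best_p = None, np.inf
        X_cur = design(selected)
        rank_cur = np.linalg.matrix_rank(X_cur)
        for name in usable:
            if name in selected:
                continue
            X_try = design(selected + [name])
            if np.linalg.matrix_rank(X_try) <= rank_cur:
                continue  # collinear with current model
            p = float(_ols(y, X_try).pvalues[-1])
            if np.isfinite(p) and p < best_p:
                best_name, best_p = name, p
        if best_name is not None and best_p <= entry_p:
            selected.append(best_name)
            changed = True
        # backward removal
        while selected:
            res = _ols(y, design(selected))
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] >= removal_p:
                del selected[worst]
                changed = True
            else:
                break
        if not changed:
            break
    return selected


def anova_lsd_contrasts(
    log_values: Sequence[float],
    phenotypes: Sequence[str],
    covariates: pd.DataFrame | None = None,
    reference: str = "gNM",
    level: float = 0.95,
) -> dict[str, ContrastResult]:
    """ANOVA of a log endpoint on phenotype class with LSD contrasts vs gNM.

    Fits ``log_value ~ class + covariates`` by OLS; each non-reference class
    coefficient is the adjusted log-GM difference from the reference, so the
    back-transformed contrast is a geometric-mean ratio.  CIs use the
    t-quantile at the pooled residual df (Fisher's LSD standard error);
    p-values are unadjusted.
    """
    y = np.asarray(log_values, dtype=float)
    cls = pd.Series(list(phenotypes))
    if not np.all(np.isfinite(y)):
        raise ValueError("log values must be finite")
    present = [c for c in sorted(cls.unique(), key=lambda c: PHENOTYPE_CODES.get(c, 99))]
    if reference not in present:
        raise ValueError(f"reference class {reference!r} absent from the cohort")
    if len(present) < 2:
        raise ValueError("need at least two phenotype classes")
    others = [c for c in present if c != reference]
    cols = [np.ones(y.size)]
    for c in others:
        cols.append((cls == c).to_numpy(dtype=float))
    if covariates is not None and covariates.shape[1]:
        for name in covariates.columns:
            cols.append(np.asarray(covariates[name], dtype=float))
    res = _ols(y, np.column_stack(cols))
    df_resid = float(res.df_resid)
    tcrit = st.t.ppf(0.5 + level / 2.0, df_resid) if df_resid > 0 else float("nan")
    out: dict[str, ContrastResult] = {}
    for i, c in enumerate(others, start=1):
        coef = float(res.params[i])
        se = float(res.bse[i])
        p = float(res.pvalues[i])
        if se == 0 or not np.isfinite(se):  # degenerate zero-residual fit
            lo = hi = np.exp(coef)
            p = 0.0 if coef != 0 else 1.0
        else:
            lo = np.exp(coef - tcrit * se)
            hi = np.exp(coef + tcrit * se)
        out[c] = ContrastResult(
            ratio=float(np.exp(coef)),
            ci_low=float(lo),
            ci_high=float(hi),
            p_value=p,
            log_diff=coef,
            se=se,
            df=df_resid,
        )
    return out


def table1_report(
    panel: pd.DataFrame,
    endpoints: Sequence[str],
    phenotype_col: str = "phenotype",
    covariate_candidates: pd.DataFrame | None = None,
    reference: str = "gNM",
) -> pd.DataFrame:
    """Cohort summary report: per endpoint and class, GM (CI), ratio to gNM, p.

    Covariates are selected once per endpoint by :func:`stepwise_covariates`
    and then held fixed in the ANOVA.  Both the raw (unadjusted) and the
    covariate-adjusted ratios are reported; they coincide when no covariate
    is selected.
    """
    rows = []
    cls = panel[phenotype_col]
    for endpoint in endpoints:
        values = panel[endpoint].astype(float)
        if (values <= 0).any():
            raise ValueError(f"endpoint {endpoint!r} has non-positive values")
        logs = np.log(values)
        selected: list[str] = []
        cov = None
        if covariate_candidates is not None and covariate_candidates.shape[1]:
            selected = stepwise_covariates(logs, covariate_candidates)
            if selected:
                cov = covariate_candidates[selected]
        raw = anova_lsd_contrasts(logs, cls, covariates=None, reference=reference)
        adj = anova_lsd_contrasts(logs, cls, covariates=cov, reference=reference)
        sums = group_summaries(values, cls)
        for c, summ in sums.items():
            is_ref = c == reference
            rows.append(
                {
                    "feature": endpoint,
                    "phenotype": c,
                    "n": summ.n,
                    "gm": summ.gm,
                    "gm_ci_low": summ.ci_low,
                    "gm_ci_high": summ.ci_high,
                    "ratio_raw": 1.0 if is_ref else raw[c].ratio,
                    "ratio_adj": 1.0 if is_ref else adj[c].ratio,
                    "ratio_ci_low": np.nan if is_ref else adj[c].ci_low,
                    "ratio_ci_high": np.nan if is_ref else adj[c].ci_high,
                    "p_value": np.nan if is_ref else adj[c].p_value,
                    "covariates": ",".join(selected),
                }
            )
    return pd.DataFrame(rows)
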