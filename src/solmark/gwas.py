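"""Per-variant additive-dosage association scan for log biomarker endpoints.

Each variant's allele dosage (0-2 copies of the alternate allele) enters a
linear regression of the log-transformed endpoint with any selected
demographic covariates as fixed terms; the per-allele slope, its standard
error and a Wald p-value are reported, and p < 5e-8 marks genome-wide
significance.  Missing dosages are mean-imputed per variant; monomorphic
variants are skipped with a reason rather than fitted.

The scan residualizes the endpoint and every dosage on the covariate
design once (Frisch-Waugh), which reproduces the full per-variant OLS fit
exactly while staying vectorized across thousands of variants.  Linkage
disequilibrium is summarized as the squared Pearson correlation of dosage
vectors, and a conditional re-scan (top variant's dosage added as a
covariate) distinguishes independent signals from LD shadows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "GENOME_WIDE_ALPHA",
    "DosageMatrix",
    "read_dosage_table",
    "write_dosage_table",
    "read_vcf_dosages",
    "ld_r2",
    "association_scan",
    "conditional_scan",
    "genome_wide_hits",
    "manhattan_table",
]

GENOME_WIDE_ALPHA = 5e-8


@dataclass
class DosageMatrix:
    """Subjects-by-variants dosages in [0, 2] with 1-based variant coordinates."""

    dosages: np.ndarray            # (n_subjects, n_variants); NaN = missing
    variants: pd.DataFrame         # columns: id, chrom, pos
    subject_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant metadata does not match dosage columns")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("dosages must lie in [0, 2]")
        for col in ("id", "chrom", "pos"):
            if col not in self.variants.columns:
                raise ValueError(f"variant table lacks column {col!r}")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the variant mean."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            all_missing = np.isnan(d).all(axis=0)
            d[:, all_missing] = 0.0  # degenerate; callers skip as unusable
            with np.errstate(invalid="ignore"):
                means = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            means[all_missing] = 0.0
            idx = np.where(np.isnan(d))
            d[idx] = means[idx[1]]
        return d

    def column(self, variant_id: str) -> np.ndarray:
        hits = np.flatnonzero((self.variants["id"] == variant_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"variant {variant_id!r} not in matrix")
        return self.imputed()[:, hits[0]]


def read_dosage_table(path, sep: str = "\t") -> DosageMatrix:
    """Read a variants-by-subjects dosage table (columns: id, chrom, pos, subjects...)."""
    df = pd.read_csv(path, sep=sep)
    meta = df[["id", "chrom", "pos"]].copy()
    subj = [c for c in df.columns if c not in ("id", "chrom", "pos")]
    dos = df[subj].to_numpy(dtype=float).T
    return DosageMatrix(dos, meta, subject_ids=subj)


def write_dosage_table(dm: DosageMatrix, path, sep: str = "\t") -> None:
    subj = list(dm.subject_ids) if dm.subject_ids is not None else [
        f"S{i:04d}" for i in range(dm.n_subjects)
    ]
    out = pd.concat(
        [dm.variants.reset_index(drop=True),
         pd.DataFrame(dm.dosages.T, columns=subj)],
        axis=1,
    )
    out.to_csv(path, sep=sep, index=False)


def read_vcf_dosages(path) -> DosageMatrix:
    """Minimal VCF reader: GT field only, alternate-allele dosage per subject."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows, ids, chroms, poss = [], [], [], []
    code = {0: 0.0, 1: 1.0, 3: 2.0, 2: np.nan}  # cyvcf2 gt_types
    for v in vcf:
        rows.append([code.get(int(g), np.nan) for g in v.gt_types])
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
    meta = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return DosageMatrix(np.asarray(rows, dtype=float).T, meta, subject_ids=subjects)


def ld_r2(a: Sequence[float], b: Sequence[float]) -> float:
    """Linkage disequilibrium as squared Pearson correlation of dosages."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("LD r^2 undefined for a monomorphic variant")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _covariate_design(n: int, covariates) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariates not aligned with subjects")
        cols.append(C)
    X = np.column_stack(cols) if len(cols) > 1 else cols[0][:, None]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    return X


def association_scan(
    dm: DosageMatrix,
    y: Sequence[float],
    covariates=None,
) -> pd.DataFrame:
    """Additive-coding linear-regression scan of every variant.

    Returns one row per variant: ``id, chrom, pos, beta, se, t, p, n, note``.
    Monomorphic variants (zero dosage variance after imputation) carry NaN
    statistics and ``note="monomorphic"``.
    """
    yv = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(yv)):
        raise ValueError("endpoint must be finite")
    if yv.size != dm.n_subjects:
        raise ValueError("endpoint not aligned with subjects")
    n = yv.size
    X = _covariate_design(n, covariates)
    p_cov = X.shape[1]
    # residualize endpoint and dosages on the covariate design (Frisch-Waugh)
    Q, _ = np.linalg.qr(X)
    G = dm.imputed()
    y_t = yv - Q @ (Q.T @ yv)
    G_t = G - Q @ (Q.T @ G)
    gss = np.einsum("ij,ij->j", G_t, G_t)
    mono = G.std(axis=0) == 0
    df = n - p_cov - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (G_t.T @ y_t) / gss
        rss = (y_t @ y_t) - beta**2 * gss
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / df / gss)
        tstat = beta / se
    p = 2.0 * st.t.sf(np.abs(tstat), df)
    out = dm.variants.copy().reset_index(drop=True)
    out["beta"] = beta
    out["se"] = se
    out["t"] = tstat
    out["p"] = p
    out["n"] = n
    out["note"] = ""
    out.loc[mono, ["beta", "se", "t", "p"]] = np.nan
    out.loc[mono, "note"] = "monomorphic"
    all_missing = np.isnan(dm.dosages).all(axis=0)
    out.loc[all_missing, ["beta", "se", "t", "p"]] = np.nan
    out.loc[all_missing, "note"] = "all-missing"
    return out


def conditional_scan(
    dm: DosageMatrix,
    y: Sequence[float],
    covariates=None,
    adjust_for: str = "",
) -> pd.DataFrame:
    """Re-scan with a named variant's dosage added as a fixed covariate.

    The adjusting variant itself (and any variant identical to it) is
    skipped with a note, since conditioning on itself is meaningless.
    """
    adj = dm.column(adjust_for)
    if adj.std() == 0:
        raise ValueError(f"adjusting variant {adjust_for!r} is monomorphic")
    if covariates is None:
        cov = adj[:, None]
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cov = np.column_stack([C, adj])
    out = association_scan(dm, y, covariates=cov)
    self_rows = out["id"] == adjust_for
    G = dm.imputed()
    identical = np.all(G == adj[:, None], axis=0)
    drop = self_rows.to_numpy() | identical
    out.loc[drop, ["beta", "se", "t", "p"]] = np.nan
    out.loc[drop, "note"] = "adjusted-for"
    return out


def genome_wide_hits(results: pd.DataFrame, alpha: float = GENOME_WIDE_ALPHA) -> pd.DataFrame:
    """Variants reaching genome-wide significance (p < alpha)."""
    ok = results["p"].notna() & (results["p"] < alpha)
    return results.loc[ok].sort_values("p").reset_index(drop=True)


def manhattan_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready export: chrom, pos, -log10(p) per tested variant."""
    ok = results["p"].notna()
    out = results.loc[ok, ["chrom", "pos"]].copy()
    with np.errstate(divide="ignore"):
        out["neglog10_p"] = -np.log10(results.loc[ok, "p"].to_numpy())
    return out.reset_index(drop=True)
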