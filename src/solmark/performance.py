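"""ROC and precision-recall evaluation of biomarkers with bootstrap uncertainty.

Each evaluation task is one phenotype class against the normal-metabolizer
reference (target class labelled 1, gNM labelled 0).  Because an impaired
metabolizer has a *higher* parent concentration but *lower* metabolic
ratios, every score carries an explicit orientation: ``"high"`` means a
larger score indicates the target class, ``"low"`` the reverse (scores are
negated internally so an informative marker always has AUROC >= 0.5).

Metrics:

* AUROC — the rank statistic U / (n_pos * n_neg) with half credit for ties;
  equals the probability a random positive outranks a random negative.
* AUPRC — non-interpolated average precision (precision accumulated at each
  recall increment over distinct thresholds); its baseline is the positive
  prevalence, the value of a prevalence-matched random classifier.
* F1max — maximum over thresholds of the harmonic mean of precision/recall.

Uncertainty comes from a class-stratified percentile bootstrap (default
1000 resamples).  Paired marker comparisons reuse identical resample
indices for both markers; AUROC differences additionally get a p-value
from the correlated-ROC (DeLong) variance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "ScoreLabelSet",
    "ComparisonResult",
    "auroc",
    "average_precision",
    "aupr",
    "f1_max",
    "bootstrap_ci",
    "compare_to_reference",
    "delong_auroc_test",
]


@dataclass(frozen=True)
class ScoreLabelSet:
    """Biomarker scores with binary labels and an explicit orientation."""

    scores: np.ndarray
    labels: np.ndarray
    orientation: str = "high"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        l = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", l)
        if s.shape != l.shape or s.ndim != 1:
            raise ValueError("scores and labels must be 1-D arrays of equal length")
        if not np.all(np.isin(l, (0, 1))):
            raise ValueError("labels must be binary (target=1, reference=0)")
        if l.sum() == 0 or l.sum() == l.size:
            raise ValueError("need at least one positive and one negative")
        if self.orientation not in ("high", "low"):
            raise ValueError("orientation must be 'high' or 'low'")

    @property
    def oriented_scores(self) -> np.ndarray:
        return self.scores if self.orientation == "high" else -self.scores

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.labels.size - self.labels.sum())

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.labels.size


def _auroc_arrays(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # midranks give ties half credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _pr_points(scores: np.ndarray, labels: np.ndarray):
    """Precision/recall at each distinct descending threshold."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    l = labels[order]
    tp = np.cumsum(l)
    fp = np.cumsum(1 - l)
    distinct = np.r_[s[1:] != s[:-1], True]  # last index of each tie group
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / labels.sum()
    return precision, recall


def _average_precision_arrays(scores: np.ndarray, labels: np.ndarray) -> float:
    precision, recall = _pr_points(scores, labels)
    drecall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * drecall))


def _f1_max_arrays(scores: np.ndarray, labels: np.ndarray) -> float:
    precision, recall = _pr_points(scores, labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    return float(f1.max())


def auroc(s: ScoreLabelSet) -> float:
    """Area under the ROC curve (rank statistic; ties get half credit)."""
    return _auroc_arrays(s.oriented_scores, s.labels)


def average_precision(s: ScoreLabelSet) -> tuple[float, float]:
    """Non-interpolated average precision and its prevalence baseline."""
    return _average_precision_arrays(s.oriented_scores, s.labels), s.prevalence


def aupr(s: ScoreLabelSet) -> tuple[float, float]:
    """Alias for :func:`average_precision`."""
    return average_precision(s)


def f1_max(s: ScoreLabelSet) -> float:
    """Maximum F1 over all score thresholds."""
    return _f1_max_arrays(s.oriented_scores, s.labels)


_METRICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "auroc": _auroc_arrays,
    "auprc": _average_precision_arrays,
    "f1_max": _f1_max_arrays,
}


def _resolve_metric(metric) -> Callable[[np.ndarray, np.ndarray], float]:
    if callable(metric):
        return metric
    try:
        return _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; use one of {sorted(_METRICS)}") from None


def _stratified_indices(rng, n_pos: int, n_neg: int, n_boot: int):
    pos = rng.integers(0, n_pos, size=(n_boot, n_pos))
    neg = rng.integers(0, n_neg, size=(n_boot, n_neg))
    return pos, neg


def bootstrap_ci(
    s: ScoreLabelSet,
    metric="auroc",
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Class-stratified percentile bootstrap CI for a performance metric.

    Stratification resamples positives and negatives separately, preserving
    prevalence and guaranteeing both classes in every resample.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fn = _resolve_metric(metric)
    rng = np.random.default_rng(seed)
    sc = s.oriented_scores
    pos_sc = sc[s.labels == 1]
    neg_sc = sc[s.labels == 0]
    labels = np.r_[np.ones(pos_sc.size, dtype=int), np.zeros(neg_sc.size, dtype=int)]
    pos_idx, neg_idx = _stratified_indices(rng, pos_sc.size, neg_sc.size, n_boot)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        boot = np.r_[pos_sc[pos_idx[b]], neg_sc[neg_idx[b]]]
        stats[b] = fn(boot, labels)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class ComparisonResult:
    """Paired difference of a candidate marker from the reference marker."""

    metric: str
    delta: float           # candidate - reference, point estimate
    delta_mean: float      # bootstrap mean difference
    ci_low: float
    ci_high: float
    p_value: float | None  # correlated-ROC p for AUROC; None otherwise


def _placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    n_pos, n_neg = pos.size, neg.size
    all_ranks = rankdata(np.r_[pos, neg])
    v10 = (all_ranks[:n_pos] - rankdata(pos)) / n_neg
    v01 = 1.0 - (all_ranks[n_pos:] - rankdata(neg)) / n_pos
    return v10, v01


def delong_auroc_test(a: ScoreLabelSet, b: ScoreLabelSet) -> tuple[float, float, float]:
    """Correlated-ROC test for two markers scored on the same subjects.

    Returns ``(delta_auroc, variance_of_delta, two_sided_p)`` using the
    structural-component (placement value) variance estimator.
    """
    if not np.array_equal(a.labels, b.labels):
        raise ValueError("paired comparison requires identical labels/subjects")
    sa, sb = a.oriented_scores, b.oriented_scores
    pos = a.labels == 1
    v10a, v01a = _placements(sa[pos], sa[~pos])
    v10b, v01b = _placements(sb[pos], sb[~pos])
    auc_a, auc_b = v10a.mean(), v10b.mean()
    n_pos, n_neg = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b])) if n_pos > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b])) if n_neg > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n_pos
    var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n_neg
    delta = float(auc_a - auc_b)
    if var <= 0:
        return delta, float(max(var, 0.0)), 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return delta, float(var), float(2 * norm.sf(abs(z)))


def compare_to_reference(
    candidate: ScoreLabelSet,
    reference: ScoreLabelSet,
    metric="auprc",
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> ComparisonResult:
    """Paired stratified-bootstrap difference (candidate - reference).

    Both markers must score the same subjects with identical labels; each
    bootstrap resample uses the same subject indices for both markers.  For
    AUROC the comparison also reports a correlated-ROC p-value; for other
    metrics significance is judged from the CI alone.
    """
    if not np.array_equal(candidate.labels, reference.labels):
        raise ValueError("paired comparison requires identical labels/subjects")
    name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
    fn = _resolve_metric(metric)
    ca, cr = candidate.oriented_scores, reference.oriented_scores
    pos = candidate.labels == 1
    pos_a, neg_a = ca[pos], ca[~pos]
    pos_r, neg_r = cr[pos], cr[~pos]
    labels = np.r_[np.ones(pos_a.size, dtype=int), np.zeros(neg_a.size, dtype=int)]
    delta_point = fn(np.r_[pos_a, neg_a], labels) - fn(np.r_[pos_r, neg_r], labels)
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = _stratified_indices(rng, pos_a.size, neg_a.size, n_boot)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        pi, ni = pos_idx[b], neg_idx[b]
        deltas[b] = fn(np.r_[pos_a[pi], neg_a[ni]], labels) - fn(np.r_[pos_r[pi], neg_r[ni]], labels)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(deltas, [alpha, 1.0 - alpha])
    p = None
    if name == "auroc":
        _, _, p = delong_auroc_test(candidate, reference)
    return ComparisonResult(
        metric=name,
        delta=float(delta_point),
        delta_mean=float(deltas.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
    )
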