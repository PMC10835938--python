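"""Non-targeted-metabolomics feature screening against phenotype classes.

The screen asks which of thousands of LC-MS molecular features track the
genotype-predicted CYP2D6 metabolizer class.  Features are first robust-
scaled per feature (subtract the median, divide by the interquartile
range), then two tree-ensemble regressors — a bagged ensemble (random
forest) and a boosted ensemble (gradient-boosted trees) — are fitted to
the numeric phenotype codes (gPM=0, gIM=1, gNM=2, gUM=3) under a repeated
2-fold nested cross-validation (default 5 repeats) with randomized
hyperparameter search in the inner folds.  Association strength is the
mean decrease in impurity ("Gini importance"; for regressors the variance-
decrease analogue), averaged over all outer-fold fits; a mean importance
above 0.01 flags a feature as a significant contributor.

The tree ensembles themselves come from scikit-learn; this module's own
content is the scaling rule, the nested-CV protocol, the fold/repeat
averaging and the thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold, RandomizedSearchCV

__all__ = ["ScreenConfig", "ScreenResult", "robust_scale", "rank_importance"]


def robust_scale(X):
    """Per-feature robust scaling: (x - median) / IQR.

    Quartiles use NumPy's default linear interpolation.  Features with zero
    IQR are centred only (never divided) and flagged.  Returns
    ``(scaled, zero_iqr)`` where ``zero_iqr`` is a boolean array per feature;
    a DataFrame input comes back as a DataFrame.
    """
    is_frame = isinstance(X, pd.DataFrame)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("feature matrix must be 2-D (subjects x features)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature matrix contains missing/non-finite values")
    q25, med, q75 = np.percentile(arr, [25, 50, 75], axis=0)
    iqr = q75 - q25
    zero = iqr == 0
    scale = np.where(zero, 1.0, iqr)
    out = (arr - med) / scale
    if is_frame:
        out = pd.DataFrame(out, index=X.index, columns=X.columns)
    return out, zero


@dataclass
class ScreenConfig:
    """Nested-CV screening protocol parameters (desk-scale defaults)."""

    n_repeats: int = 5
    n_outer_folds: int = 2
    n_inner_folds: int = 2
    n_search_iter: int = 10
    importance_threshold: float = 0.01
    rf_param_distributions: Mapping[str, Sequence] = field(default_factory=lambda: {
        "n_estimators": [100, 200, 300],
        "max_depth": [3, 5, 8, None],
        "max_features": ["sqrt", 0.3, 1.0],
        "min_samples_leaf": [1, 3, 5],
    })
    gbdt_param_distributions: Mapping[str, Sequence] = field(default_factory=lambda: {
        "n_estimators": [100, 200, 300],
        "learning_rate": [0.03, 0.1, 0.3],
        "max_depth": [2, 3, 5],
        "subsample": [0.7, 1.0],
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("need repeats >= 1 and folds >= 2")
        if self.importance_threshold <= 0:
            raise ValueError("importance threshold must be > 0")


@dataclass
class ScreenResult:
    """Importance table plus outer-fold generalization scores per family."""

    table: pd.DataFrame          # per feature: importances + significance flags
    cv_scores: dict[str, float]  # mean outer-fold R^2 per learner family
    config: ScreenConfig

    def significant_features(self) -> list:
        return list(self.table.index[self.table["significant"]])


def _nested_importances(est, param_dist, X, y, cfg: ScreenConfig, rng):
    n_features = X.shape[1]
    imp = np.zeros(n_features)
    scores = []
    n_fits = 0
    for rep in range(cfg.n_repeats):
        outer = KFold(cfg.n_outer_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        for train, test in outer.split(X):
            search = RandomizedSearchCV(
                est,
                param_dist,
                n_iter=cfg.n_search_iter,
                cv=KFold(cfg.n_inner_folds, shuffle=True,
                         random_state=int(rng.integers(2**31 - 1))),
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=None,
            )
            search.fit(X[train], y[train])
            best = search.best_estimator_
            imp += best.feature_importances_
            scores.append(best.score(X[test], y[test]))
            n_fits += 1
    return imp / n_fits, float(np.mean(scores))


def rank_importance(
    features,
    target: Sequence[float],
    cfg: ScreenConfig | None = None,
) -> ScreenResult:
    """Rank features by mean impurity-decrease importance under nested CV.

    ``features`` is a subjects-by-features matrix (DataFrame column names
    become feature ids); ``target`` the numeric phenotype codes.  Importances
    are averaged across all outer-fold refits of both learner families; the
    ``significant`` flag marks features whose mean importance exceeds the
    threshold in either family.
    """
    cfg = cfg or ScreenConfig()
    names = list(features.columns) if isinstance(features, pd.DataFrame) else None
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be 2-D with one row per target value")
    if np.unique(y).size < 2:
        raise ValueError("target must take at least two distinct values")
    rng = np.random.default_rng(cfg.seed)
    seed_rf = int(rng.integers(2**31 - 1))
    seed_gb = int(rng.integers(2**31 - 1))
    rf_imp, rf_score = _nested_importances(
        RandomForestRegressor(random_state=seed_rf),
        dict(cfg.rf_param_distributions), X, y, cfg, rng,
    )
    gb_imp, gb_score = _nested_importances(
        GradientBoostingRegressor(random_state=seed_gb),
        dict(cfg.gbdt_param_distributions), X, y, cfg, rng,
    )
    table = pd.DataFrame(
        {
            "rf_importance": rf_imp,
            "gbdt_importance": gb_imp,
        },
        index=names if names is not None else pd.RangeIndex(X.shape[1]),
    )
    thr = cfg.importance_threshold
    table["rf_significant"] = table["rf_importance"] > thr
    table["gbdt_significant"] = table["gbdt_importance"] > thr
    table["significant"] = table["rf_significant"] | table["gbdt_significant"]
    return ScreenResult(
        table=table,
        cv_scores={"random_forest": rf_score, "gbdt": gb_score},
        config=cfg,
    )
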