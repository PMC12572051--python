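"""Cross-fitted nuisance estimation: propensity and per-arm outcome models.

Every row's propensity score pi(X) and potential-outcome predictions g(1, X),
g(0, X) come from models trained on the other folds of a random partition, so
no observation is ever predicted by a model that saw it.  Random forests
follow the reference configuration (500 trees, sqrt-of-p feature subsets,
maximum depth tuned over a fixed grid by 3-fold cross-validated log-loss);
an L1-penalized logistic regression is available as the alternative learner.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

DEPTH_GRID = (3, 4, 6, 8, 10, 12, 14, 16, 18, 20)


@dataclass(frozen=True)
class LearnerSpec:
    kind: str = "random_forest"  # or "lasso"
    depth_grid: tuple = DEPTH_GRID
    cv_folds: int = 3
    n_trees: int = 500
    # L1 penalty candidates (lasso only); a single value skips CV selection
    lasso_Cs: tuple = (0.001, 0.01, 0.1, 1.0, 10.0)
    clip: tuple = (0.01, 0.99)

    def __post_init__(self) -> None:
        if self.kind not in ("random_forest", "lasso"):
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if not self.depth_grid:
            raise ValueError("depth grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.lasso_Cs:
            raise ValueError("lasso_Cs must be non-empty")


@dataclass(frozen=True)
class CrossfitPlan:
    K: int = 5
    resample_index: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")


@dataclass
class NuisancePredictions:
    """Out-of-fold predictions covering every sample row."""

    pi: np.ndarray
    g1: np.ndarray
    g0: np.ndarray
    fold: np.ndarray
    clip: tuple = (0.01, 0.99)


def partition(ids, K: int, seed: int) -> np.ndarray:
    """Random fold labels 0..K-1 with sizes differing by at most one."""
    n = len(ids)
    if K > n:
        raise ValueError(f"cannot split {n} observations into {K} folds")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for k, chunk in enumerate(np.array_split(perm, K)):
        labels[chunk] = k
    return labels


class _ConstantModel:
    """Fallback when a training target is single-class."""

    def __init__(self, p: float):
        self.p = float(p)

    def predict_proba_1(self, X) -> np.ndarray:
        return np.full(len(X), self.p)


class _SklearnModel:
    def __init__(self, est):
        self.est = est

    def predict_proba_1(self, X) -> np.ndarray:
        proba = self.est.predict_proba(X)
        return proba[:, list(self.est.classes_).index(1)]


def _rf(depth: int, spec: LearnerSpec, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_depth=depth,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )


def tune_depth(X, y, spec: LearnerSpec, seed: int) -> int:
    """Grid value minimizing cross-validated log-loss on the training rows."""
    y = np.asarray(y)
    grid = sorted(spec.depth_grid)
    if len(np.unique(y)) < 2:
        warnings.warn("degenerate training target; returning smallest depth")
        return grid[0]
    if len(grid) == 1:
        return grid[0]
    if len(y) < spec.cv_folds:
        raise ValueError("fewer training rows than CV folds")
    X = np.asarray(X, dtype=float)
    n_splits = min(spec.cv_folds, int(np.bincount(y.astype(int)).min()))
    if n_splits < 2:
        warnings.warn("too few minority observations to cross-validate; smallest depth")
        return grid[0]
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    best_depth, best_loss = grid[0], np.inf
    for depth in grid:
        losses = []
        for tr, te in cv.split(X, y):
            if len(np.unique(y[tr])) < 2:
                continue
            model = _rf(depth, spec, seed).fit(X[tr], y[tr])
            p = _SklearnModel(model).predict_proba_1(X[te])
            losses.append(log_loss(y[te], np.clip(p, 1e-9, 1 - 1e-9), labels=[0, 1]))
        loss = float(np.mean(losses)) if losses else np.inf
        if loss < best_loss:
            best_depth, best_loss = depth, loss
    return best_depth


def _fit_binary(X, y, spec: LearnerSpec, seed: int):
    """Fit one nuisance model on training rows; constant model if degenerate."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        return _ConstantModel(float(y.mean()))
    if spec.kind == "random_forest":
        depth = tune_depth(X, y, spec, seed)
        return _SklearnModel(_rf(depth, spec, seed).fit(X, y))
    if len(spec.lasso_Cs) == 1:
        final = LogisticRegression(
            C=spec.lasso_Cs[0], l1_ratio=1.0, solver="liblinear",
            random_state=seed, max_iter=200,
        )
    else:
        final = LogisticRegressionCV(
            Cs=list(spec.lasso_Cs),
            cv=spec.cv_folds,
            l1_ratios=(1.0,),
            solver="liblinear",
            scoring="neg_log_loss",
            random_state=seed,
            max_iter=200,
            use_legacy_attributes=False,
        )
    est = make_pipeline(StandardScaler(), final)
    est.fit(np.asarray(X, dtype=float), y)
    return _SklearnModel(est)


def _valid_partition(labels: np.ndarray, t: np.ndarray, K: int) -> bool:
    for k in range(K):
        train = labels != k
        if t[train].sum() == 0 or (1 - t[train]).sum() == 0:
            return False
    return True


def fit_predict_crossfit(
    sample, spec: LearnerSpec, plan: CrossfitPlan, max_redraws: int = 10
) -> NuisancePredictions:
    """K-fold cross-fitted pi(X), g(1, X), g(0, X) for every sample row.

    Depth tuning (random forest) or penalty selection (lasso) happens
    independently inside every training fold.  Propensities are clipped to
    ``spec.clip``.
    """
    X = np.asarray(sample.X, dtype=float)
    y = np.asarray(sample.y, dtype=float)
    t = np.asarray(sample.t, dtype=int)
    n = len(y)
    if t.sum() == 0 or t.sum() == n:
        raise ValueError("sample must contain both treated and control rows")

    ss = np.random.SeedSequence([int(plan.seed), int(plan.resample_index)])
    part_seeds = ss.spawn(max_redraws + 1)
    labels = None
    for attempt, child in enumerate(part_seeds):
        cand = partition(np.arange(n), plan.K, child.generate_state(1)[0])
        if _valid_partition(cand, t, plan.K):
            labels = cand
            if attempt:
                logger.info("redrew partition %d time(s) to get both arms per fold", attempt)
            break
    if labels is None:
        raise RuntimeError(
            f"no partition with both arms in every training fold after "
            f"{max_redraws + 1} draws; sample too small or too unbalanced"
        )

    pi = np.empty(n)
    g1 = np.empty(n)
    g0 = np.empty(n)
    fold_seeds = ss.spawn(plan.K)
    for k in range(plan.K):
        train = labels != k
        test = labels == k
        seeds = fold_seeds[k].generate_state(3)
        m_pi = _fit_binary(X[train], t[train], spec, int(seeds[0] % (2**31)))
        m_g1 = _fit_binary(X[train & (t == 1)], y[train & (t == 1)], spec, int(seeds[1] % (2**31)))
        m_g0 = _fit_binary(X[train & (t == 0)], y[train & (t == 0)], spec, int(seeds[2] % (2**31)))
        pi[test] = m_pi.predict_proba_1(X[test])
        g1[test] = m_g1.predict_proba_1(X[test])
        g0[test] = m_g0.predict_proba_1(X[test])
    lo, hi = spec.clip
    return NuisancePredictions(
        pi=np.clip(pi, lo, hi),
        g1=np.clip(g1, 0.0, 1.0),
        g0=np.clip(g0, 0.0, 1.0),
        fold=labels,
        clip=spec.clip,
    )
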