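"""Cross-validated risk models.

Two classifiers produce the tachycardia risk score: L1-regularized
(lasso) logistic regression and a random forest.  Both are trained with
k-fold cross-validation (10 folds by default): each window is scored by
the one fold model that never saw it, and the out-of-fold scores are
pooled to express performance.  Folds are stratified by class and, by
default, grouped by subject so no subject contributes windows to both
the training and test side of a fold.

Missing feature values are median-imputed inside each fold using
training-fold medians only; the lasso penalty weight is chosen by a
nested cross-validation inside each training fold; the forest uses 500
trees with sqrt(p) features per split and no depth cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import PipelineConfig

ALGORITHMS = ("lasso_logistic", "random_forest")


@dataclass
class ModelBundle:
    """A cross-validated model: fold pipelines plus pooled scores."""

    algorithm: str
    feature_names: list[str]
    fold_models: list[Pipeline]
    fold_of: np.ndarray          # fold index of each training window
    oof_scores: np.ndarray       # pooled out-of-fold scores, one per window
    rng_seed: int

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Score new windows: mean of the fold models' probabilities."""
        X = _as_matrix(X, self.feature_names)
        preds = [m.predict_proba(X)[:, 1] for m in self.fold_models]
        return np.mean(preds, axis=0)


def _as_matrix(X, feature_names: list[str]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X[feature_names].to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 31 + fold + 1) % (2**31 - 1)


def _make_pipeline(algorithm: str, cfg: PipelineConfig, seed: int) -> Pipeline:
    steps = [("impute", SimpleImputer(strategy="median"))]
    if algorithm == "lasso_logistic":
        steps += [
            ("scale", StandardScaler()),
            ("clf", LogisticRegressionCV(
                Cs=10, cv=cfg.lasso_inner_folds, penalty="l1",
                solver="liblinear", scoring="roc_auc",
                random_state=seed, max_iter=2000)),
        ]
    elif algorithm == "random_forest":
        steps.append(("clf", RandomForestClassifier(
            n_estimators=cfg.rf_n_trees, max_features="sqrt",
            random_state=seed, n_jobs=1)))
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; "
                         f"choose one of {ALGORITHMS}")
    return Pipeline(steps)


def assign_folds(y: np.ndarray, groups: np.ndarray | None,
                 cfg: PipelineConfig) -> np.ndarray:
    """Stratified (optionally subject-grouped) fold labels, 0..n_folds-1."""
    y = np.asarray(y)
    idx = np.arange(y.size)
    if groups is not None and cfg.group_by_subject:
        splitter = StratifiedGroupKFold(n_splits=cfg.n_folds, shuffle=True,
                                        random_state=cfg.rng_seed)
        splits = splitter.split(idx.reshape(-1, 1), y, groups)
    else:
        splitter = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                                   random_state=cfg.rng_seed)
        splits = splitter.split(idx.reshape(-1, 1), y)
    fold_of = np.full(y.size, -1, dtype=int)
    for fold, (_, test_idx) in enumerate(splits):
        fold_of[test_idx] = fold
    return fold_of


def crossval_train(features: pd.DataFrame, labels: np.ndarray,
                   algorithm: str, cfg: PipelineConfig,
                   groups: np.ndarray | None = None,
                   fold_assignment: np.ndarray | None = None) -> ModelBundle:
    """Train fold models and pool out-of-fold risk scores.

    ``features`` holds one row per window with the 42 feature columns
    (extra metadata columns are ignored); ``labels`` is binary (1 = case).
    ``fold_assignment`` may pin a precomputed fold label per window;
    otherwise folds are drawn stratified (and subject-grouped when
    ``groups`` is given) under ``cfg.rng_seed``.
    """
    from .features import FEATURE_NAMES

    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    feature_names = [c for c in features.columns if c in FEATURE_NAMES] \
        if isinstance(features, pd.DataFrame) else list(FEATURE_NAMES)
    if not feature_names:
        feature_names = list(features.columns)
    X = _as_matrix(features, feature_names)
    for cls in (0, 1):
        if (y == cls).sum() < cfg.n_folds:
            raise ValueError(
                f"class {cls} has fewer than n_folds={cfg.n_folds} windows; "
                "use fewer folds")

    fold_of = (np.asarray(fold_assignment, dtype=int)
               if fold_assignment is not None
               else assign_folds(y, groups, cfg))

    fold_models: list[Pipeline] = []
    oof = np.full(y.size, np.nan)
    for fold in sorted(set(fold_of[fold_of >= 0])):
        train = fold_of != fold
        test = fold_of == fold
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                f"fold {fold}: a class is absent from the training split; "
                "use fewer folds")
        pipe = _make_pipeline(algorithm, cfg, _fold_seed(cfg.rng_seed, fold))
        pipe.fit(X[train], y[train])
        oof[test] = pipe.predict_proba(X[test])[:, 1]
        fold_models.append(pipe)

    return ModelBundle(algorithm, feature_names, fold_models, fold_of, oof,
                       cfg.rng_seed)


def evaluate(bundle: ModelBundle, labels: np.ndarray
             ) -> tuple[dict[str, float], pd.DataFrame]:
    """AUC (trapezoidal over the empirical ROC), accuracy at 0.5, ROC points."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation needs both classes present")
    scores = bundle.oof_scores
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    accuracy = float(np.mean((scores >= 0.5).astype(int) == y))
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr,
                               "threshold": thresholds})
    return {"auc": auc, "accuracy": accuracy, "n": int(y.size),
            "prevalence": float(y.mean())}, roc_points


def feature_ranking(bundle: ModelBundle, top_k: int = 15) -> list[str]:
    """Features ordered by importance, ties broken alphabetically.

    Random forest: mean impurity importance across fold models.  Lasso:
    mean absolute standardized coefficient (the coefficient on the scaled
    design, averaged over folds).
    """
    scores = importance_table(bundle)
    ordered = scores.sort_values(["importance", "feature"],
                                 ascending=[False, True])
    return ordered["feature"].head(min(top_k, len(ordered))).tolist()


def importance_table(bundle: ModelBundle) -> pd.DataFrame:
    """Per-feature mean importance across fold models."""
    per_fold = []
    for pipe in bundle.fold_models:
        clf = pipe.named_steps["clf"]
        if bundle.algorithm == "random_forest":
            per_fold.append(clf.feature_importances_)
        else:
            per_fold.append(np.abs(clf.coef_.ravel()))
    mean_imp = np.mean(per_fold, axis=0)
    return pd.DataFrame({"feature": bundle.feature_names,
                         "importance": mean_imp})
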