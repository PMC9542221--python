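"""Survival classification with nested cross-validated model selection.

The classifier dichotomizes survival at a fixed threshold (default 480
days) and selects, per outer fold, the (model family, feature count)
combination with the lowest mean inner-fold Brier score; each outer
fold's inner winner becomes a candidate, candidates are compared by
outer-validation AUC, and the overall winner is refit on all training
rows with its feature recipe.  Feature selection (mRMR) is re-run inside
every outer training split so no test information leaks into selection.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .radiomics import MRMRSelector

__all__ = [
    "default_model_grid",
    "small_model_grid",
    "brier_score",
    "NestedCVSurvivalClassifier",
    "nested_cv_select",
    "evaluate_rs",
]


def default_model_grid(seed: int = 0) -> dict[str, BaseEstimator]:
    """The five examined model families."""
    return {
        "logreg": LogisticRegression(max_iter=2000),
        "svm": SVC(kernel="linear", probability=True, random_state=seed),
        "xgb": XGBClassifier(n_estimators=50, max_depth=2, learning_rate=0.3,
                             eval_metric="logloss", random_state=seed,
                             n_jobs=1, verbosity=0),
        "rf": RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1),
        "knn": KNeighborsClassifier(n_neighbors=5),
    }


def small_model_grid(seed: int = 0) -> dict[str, BaseEstimator]:
    """Reduced grid for desk-scale experiment sweeps: a single calibrated
    linear family keeps the replacement comparison free of model-selection
    variance (the full five-family grid is exercised separately)."""
    return {"logreg": LogisticRegression(C=0.5, max_iter=2000)}


def brier_score(y_true, proba) -> float:
    """Mean squared error between predicted P(class 1) and the binary label."""
    y = np.asarray(y_true, float)
    p = np.asarray(proba, float)
    return float(np.mean((p - y) ** 2))


def _make_pipeline(model: BaseEstimator) -> Pipeline:
    return Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
        ("clf", clone(model)),
    ])


class NestedCVSurvivalClassifier(ClassifierMixin, BaseEstimator):
    """Nested cross-validation model selection (Brier inner, AUC outer).

    Fitted attributes
    -----------------
    outer_candidates_ : one record per outer fold (family, k, inner Brier,
        outer AUC, selected feature names)
    winner_ : the candidate with the best outer-validation AUC
    selected_features_ : ordered feature names of the final model
    family_ : model family of the final model
    outer_aucs_, outer_auc_mean_ : per-fold outer AUCs and their mean
    best_model_ : pipeline refit on all training rows with the winner recipe
    """

    def __init__(self, model_grid: Mapping[str, BaseEstimator] | None = None,
                 outer_folds: int = 5, inner_folds: int = 10,
                 k_grid: Sequence[int] = (8, 16), seed: int = 0,
                 threshold: float = 0.5, mrmr_bins: int = 8):
        self.model_grid = model_grid
        self.outer_folds = outer_folds
        self.inner_folds = inner_folds
        self.k_grid = k_grid
        self.seed = seed
        self.threshold = threshold
        # coarser MI discretization stabilizes relevance ranking on small
        # cohorts (chance-level MI scales with the bin count)
        self.mrmr_bins = mrmr_bins

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        grid = self.model_grid or default_model_grid(self.seed)
        n_min = int(min(np.sum(y == 0), np.sum(y == 1)))
        if n_min < 2:
            raise ValueError("a class is (nearly) absent; stratification impossible")
        outer_k = min(self.outer_folds, n_min)
        if outer_k < self.outer_folds:
            warnings.warn(f"outer folds reduced to {outer_k} (small class)")
        outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=self.seed)

        candidates = []
        for fold_i, (tr, va) in enumerate(outer.split(X, y)):
            Xtr, ytr = X.iloc[tr], y[tr]
            ranking = MRMRSelector(k=max(self.k_grid), n_bins=self.mrmr_bins).fit(Xtr, ytr).ranking_
            inner_min = int(min(np.sum(ytr == 0), np.sum(ytr == 1)))
            inner_k = min(self.inner_folds, inner_min)
            if inner_k < self.inner_folds:
                warnings.warn(f"inner folds reduced to {inner_k} (small class)")
            inner = StratifiedKFold(n_splits=inner_k, shuffle=True,
                                    random_state=self.seed + 1)
            best = None
            for family in sorted(grid):
                for k in self.k_grid:
                    feats = ranking[:k]
                    briers = []
                    for itr, iva in inner.split(Xtr, ytr):
                        pipe = _make_pipeline(grid[family])
                        pipe.fit(Xtr.iloc[itr][feats], ytr[itr])
                        p = pipe.predict_proba(Xtr.iloc[iva][feats])[:, 1]
                        briers.append(brier_score(ytr[iva], p))
                    mb = float(np.mean(briers))
                    if best is None or mb < best["inner_brier"] - 1e-12:
                        best = {"family": family, "k": k, "features": feats,
                                "inner_brier": mb}
            pipe = _make_pipeline(grid[best["family"]])
            pipe.fit(Xtr[best["features"]], ytr)
            pva = pipe.predict_proba(X.iloc[va][best["features"]])[:, 1]
            best["outer_auc"] = float(roc_auc_score(y[va], pva))
            best["fold"] = fold_i
            candidates.append(best)

        self.outer_candidates_ = candidates
        self.outer_aucs_ = [c["outer_auc"] for c in candidates]
        self.outer_auc_mean_ = float(np.mean(self.outer_aucs_))
        self.winner_ = max(candidates, key=lambda c: c["outer_auc"])
        self.family_ = self.winner_["family"]
        self.selected_features_ = list(self.winner_["features"])
        self.best_model_ = _make_pipeline(grid[self.family_])
        self.best_model_.fit(X[self.selected_features_], y)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _check_features(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        missing = [f for f in self.selected_features_ if f not in X.columns]
        if missing:
            raise KeyError(f"test table lacks selected features: {missing[:5]}")
        return X[self.selected_features_]

    def predict_proba(self, X) -> np.ndarray:
        return self.best_model_.predict_proba(self._check_features(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > self.threshold).astype(int)


def nested_cv_select(table: pd.DataFrame, labels,
                     model_grid: Mapping[str, BaseEstimator] | None = None,
                     seed: int = 0, outer_folds: int = 5, inner_folds: int = 10,
                     k_grid: Sequence[int] = (8, 16)) -> NestedCVSurvivalClassifier:
    """Functional wrapper over :class:`NestedCVSurvivalClassifier`."""
    return NestedCVSurvivalClassifier(
        model_grid=model_grid, outer_folds=outer_folds, inner_folds=inner_folds,
        k_grid=k_grid, seed=seed).fit(table, labels)


def evaluate_rs(model: NestedCVSurvivalClassifier, test_table: pd.DataFrame,
                test_labels) -> dict:
    """Classifier metrics macro-averaged over the two classes, plus the
    per-subject predicted probabilities for agreement analysis."""
    y = np.asarray(test_labels).astype(int)
    proba = model.predict_proba(test_table)[:, 1]
    pred = (proba > model.threshold).astype(int)
    metrics = {
        "auc": float(roc_auc_score(y, proba)) if len(np.unique(y)) > 1 else float("nan"),
        "accuracy": float(accuracy_score(y, pred)),
        "precision": float(precision_score(y, pred, average="macro", zero_division=0)),
        "recall": float(recall_score(y, pred, average="macro", zero_division=0)),
        "f1": float(f1_score(y, pred, average="macro", zero_division=0)),
    }
    probabilities = pd.Series(proba, index=pd.DataFrame(test_table).index,
                              name="proba_survival")
    return {"metrics": metrics, "probabilities": probabilities}
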