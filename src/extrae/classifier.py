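"""Supervised rule classification over the five-feature representation.

:class:`RuleClassifier` is a scikit-learn estimator wrapping a bagged
ensemble of randomized decision trees (the configuration that won the
original algorithm comparison) with two domain-specific behaviours:

* the expected input is the fixed 5-column feature matrix
  (support, confidence, lift, n_antecedents, n_consequents);
* a single-class training set degenerates to a constant predictor instead
  of failing, because the tiny seeds that bootstrap the semi-supervised
  loop can easily be class-skewed.

Any estimator with ``fit``/``predict``/``predict_proba`` can be plugged
into the loop in its place.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    auc,
    f1_score,
    precision_recall_curve,
    roc_auc_score,
)
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .mining import FEATURE_NAMES, AssociationRule, RuleFeatures

__all__ = [
    "LabeledRule",
    "RuleClassifier",
    "Metrics",
    "train",
    "predict",
    "evaluate",
    "evaluate_scores",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class LabeledRule:
    """A rule with features, p-value, label, and the label's provenance.

    ``label_source`` is ``"gold"`` for human/oracle annotations and
    ``"agreed"`` for labels assigned by prediction agreement during the
    incremental loop.
    """

    rule: AssociationRule
    features: RuleFeatures
    p_value: float
    label: bool
    label_source: str = "gold"

    def __post_init__(self) -> None:
        if self.label_source not in ("gold", "agreed"):
            raise ValueError("label_source must be 'gold' or 'agreed'")


class RuleClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest true/false rule classifier on the 5 rule features.

    Parameters
    ----------
    n_estimators : int, default 100
        Trees in the ensemble.
    max_features : {"sqrt", "log2", int, float, None}, default "sqrt"
        Features considered per split (sqrt of 5 ~ 2).
    max_depth : int or None, default None
        Unlimited depth by default.
    bootstrap : bool, default True
    random_state : int or None
        Fixing it makes predictions a pure function of the training data.

    Attributes
    ----------
    classes_ : ndarray of shape (2,) — always [False, True].
    constant_ : bool or None — the constant prediction if the training set
        had a single class, else None.
    forest_ : the fitted sklearn forest (absent in the constant case).
    training_manifest_ : dict recording n_examples, class counts, seed and
        hyperparameters of the fit.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_features="sqrt",
        max_depth: int | None = None,
        bootstrap: bool = True,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.max_depth = max_depth
        self.bootstrap = bootstrap
        self.random_state = random_state

    def fit(self, X, y) -> "RuleClassifier":
        X, y = check_X_y(X, y)
        if X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} features {FEATURE_NAMES}, "
                f"got {X.shape[1]}"
            )
        y = np.asarray(y).astype(bool)
        self.classes_ = np.array([False, True])
        self.n_features_in_ = X.shape[1]
        n_true = int(y.sum())
        self.training_manifest_ = {
            "n_examples": int(len(y)),
            "class_counts": {"true": n_true, "false": int(len(y) - n_true)},
            "rng_seed": self.random_state,
            "hyperparameters": {
                "n_estimators": self.n_estimators,
                "max_features": self.max_features,
                "max_depth": self.max_depth,
                "bootstrap": self.bootstrap,
            },
        }
        if n_true == 0 or n_true == len(y):
            self.constant_ = bool(y[0])
            return self
        self.constant_ = None
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            bootstrap=self.bootstrap,
            random_state=self.random_state,
        ).fit(X, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        if self.constant_ is not None:
            col = np.full(len(X), 1.0 if self.constant_ else 0.0)
            return np.column_stack([1.0 - col, col])
        proba = self.forest_.predict_proba(X)
        # forest classes_ is [False, True] already (bool sort order)
        return proba

    def predict(self, X) -> np.ndarray:
        """True iff the estimated true-class probability is >= 0.5."""
        return self.predict_proba(X)[:, 1] >= 0.5

    def decision_scores(self, X) -> np.ndarray:
        """True-class probability estimates in [0, 1]."""
        return self.predict_proba(X)[:, 1]


@dataclass(frozen=True)
class Metrics:
    """Test-set metrics; AUCs are None when undefined (single-class truth)."""

    f_measure: float
    auc_roc: float | None
    au_prc: float | None
    accuracy: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def evaluate_scores(y_true, scores, threshold: float = 0.5) -> Metrics:
    """Metrics from true labels and true-class scores.

    F-measure is the harmonic mean of precision and recall for the positive
    (true-rule) class at ``score >= threshold``; AUC-ROC comes from the
    score ranking and AU-PRC is the trapezoidal area under the
    precision-recall curve.  With single-class truth both AUCs are None.
    """
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if len(y_true) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    y_pred = scores >= threshold
    f = float(f1_score(y_true, y_pred, zero_division=0.0))
    acc = float(accuracy_score(y_true, y_pred))
    if y_true.all() or not y_true.any():
        return Metrics(f, None, None, acc)
    auc_roc = float(roc_auc_score(y_true, scores))
    precision, recall, _ = precision_recall_curve(y_true, scores)
    au_prc = float(auc(recall, precision))
    return Metrics(f, auc_roc, au_prc, acc)


# --- thin functional wrappers over the estimator --------------------------


def train(
    examples: Sequence[LabeledRule],
    rng_seed: int = 0,
    hyperparameters: Mapping | None = None,
) -> RuleClassifier:
    """Fit a :class:`RuleClassifier` on labeled rules."""
    if len(examples) == 0:
        raise ValueError("cannot train on an empty example list")
    X = np.vstack([ex.features.to_array() for ex in examples])
    y = np.array([ex.label for ex in examples])
    clf = RuleClassifier(random_state=rng_seed, **dict(hyperparameters or {}))
    return clf.fit(X, y)


def predict(model: RuleClassifier, features: RuleFeatures) -> tuple[bool, float]:
    """Single-rule prediction: (label, true-class score)."""
    score = float(model.decision_scores(features.to_array().reshape(1, -1))[0])
    return score >= 0.5, score


def evaluate(model: RuleClassifier, test: Sequence[LabeledRule]) -> Metrics:
    """Evaluate a fitted model against gold-labeled rules."""
    if len(test) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    X = np.vstack([ex.features.to_array() for ex in test])
    y = np.array([ex.label for ex in test])
    return evaluate_scores(y, model.decision_scores(X))


def save_model(model: RuleClassifier, path: str | Path) -> None:
    """Serialize a fitted model (manifest embedded) to one artifact file."""
    check_is_fitted(model, "classes_")
    joblib.dump({"model": model, "manifest": model.training_manifest_}, path)


def load_model(path: str | Path) -> RuleClassifier:
    return joblib.load(path)["model"]
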