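"""The EXTRAE semi-supervised incremental loop.

Starting from a tiny gold-labeled *seed* of p-valued rules and a large
unlabeled *development* pool, each iteration

1. trains the supervised classifier on the current seed labels,
2. picks the p-value threshold maximizing hits on the seed,
3. predicts each development rule twice — supervised (classifier) and
   unsupervised (p <= threshold),
4. promotes the *coincident* rules, where both predictions agree, into the
   seed carrying the agreed label, and
5. repeats until no rule is coincident.

Development gold labels are never read inside the loop; they exist only
for post-hoc evaluation.  Because every non-final iteration strictly
shrinks the development pool, termination within |development| + 1
iterations is guaranteed.

:class:`ExtraeClassifier` packages the loop as a scikit-learn
semi-supervised classifier: ``fit(X, y)`` takes the 5 rule features plus a
p-value column and labels in {0, 1, -1}, with -1 marking unlabeled rules
(the convention of ``sklearn.semi_supervised``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .classifier import LabeledRule, Metrics, RuleClassifier, evaluate_scores
from .mining import FEATURE_NAMES
from .threshold import ThresholdResult, select_threshold

__all__ = [
    "SplitSpec",
    "IterationRecord",
    "ExtraeResult",
    "ExtraeClassifier",
    "split_dataset",
    "sample_seed",
    "run_iteration",
    "run_extrae",
]

N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class SplitSpec:
    """How to carve labeled rules into test / seed / development."""

    test_fraction: float = 0.2
    seed_size: int = 10
    rng_seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.seed_size < 1:
            raise ValueError("seed_size must be positive")


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    n_coincident: int
    threshold: float
    seed_size_after: int
    metrics: Metrics | None  # test-set metrics of this iteration's model

    def to_dict(self) -> dict:
        d = {
            "iteration": self.iteration,
            "n_coincident": self.n_coincident,
            "threshold": self.threshold,
            "seed_size_after": self.seed_size_after,
        }
        if self.metrics is not None:
            d.update(self.metrics.to_dict())
        return d


@dataclass
class ExtraeResult:
    trace: list[IterationRecord]
    final_model: RuleClassifier
    final_seed: list[LabeledRule]
    unresolved: list[LabeledRule]
    test: list[LabeledRule]
    final_metrics: Metrics | None

    def trace_json(self) -> str:
        return json.dumps([r.to_dict() for r in self.trace], sort_keys=True)


class ExtraeClassifier(ClassifierMixin, BaseEstimator):
    """Semi-supervised rule classifier (classifier / p-value-filter agreement).

    Parameters
    ----------
    base_estimator : estimator or None
        The supervised module; a fresh clone is fitted each iteration.
        Defaults to :class:`~extrae.classifier.RuleClassifier`.
    max_iter : int, default 100
        Safety cap; the loop normally stops when no rule is coincident.
    random_state : int or None
        Seeds the per-iteration classifier fits.

    ``fit(X, y)`` expects ``X`` of shape (n_rules, 6): the five rule
    features in canonical order followed by the rule's Fisher p-value.
    ``y`` holds 1/0 (or True/False) for seed rules and -1 for unlabeled
    development rules.  P-values are intrinsic rule attributes computed
    once, up front; only the threshold changes across iterations.

    Attributes
    ----------
    classifier_ : the final fitted supervised module.
    threshold_ : float — p-value threshold of the final iteration.
    trace_ : list of IterationRecord.
    transduction_ : ndarray — final labels; -1 where never agreed.
    label_sources_ : ndarray of {"gold", "agreed", "unresolved"}.
    n_iter_ : iterations executed.
    """

    _parameter_constraints: dict = {}

    def __init__(
        self,
        base_estimator=None,
        max_iter: int = 100,
        random_state: int | None = None,
    ):
        self.base_estimator = base_estimator
        self.max_iter = max_iter
        self.random_state = random_state

    def _split_X(self, X):
        X = check_array(X)
        if X.shape[1] != N_FEATURES + 1:
            raise ValueError(
                f"X must have {N_FEATURES + 1} columns: {FEATURE_NAMES} + p_value"
            )
        return X[:, :N_FEATURES], X[:, N_FEATURES]

    def fit(self, X, y, eval_set: tuple | None = None) -> "ExtraeClassifier":
        """Run the incremental loop.

        ``eval_set=(X_test, y_test)`` (same 6-column layout) triggers
        per-iteration test evaluation recorded in ``trace_``.
        """
        X, y = check_X_y(X, y)
        F, p = self._split_X(X)
        y = np.asarray(y, dtype=int)
        if not set(np.unique(y)) <= {-1, 0, 1}:
            raise ValueError("y must contain only -1 (unlabeled), 0 and 1")
        seed_mask = y != -1
        if not seed_mask.any():
            raise ValueError("at least one labeled seed rule is required")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

        eval_F = eval_p = eval_y = None
        if eval_set is not None:
            X_test, y_test = eval_set
            eval_F, eval_p = self._split_X(X_test)
            eval_y = np.asarray(y_test).astype(bool)

        labels = y.copy()  # working labels; -1 = still unlabeled
        sources = np.where(seed_mask, "gold", "unresolved").astype(object)
        base = (
            self.base_estimator
            if self.base_estimator is not None
            else RuleClassifier(random_state=self.random_state)
        )

        trace: list[IterationRecord] = []
        for it in range(self.max_iter):
            in_seed = labels != -1
            clf = clone(base)
            if "random_state" in clf.get_params():
                clf.set_params(random_state=self.random_state)
            clf.fit(F[in_seed], labels[in_seed].astype(bool))
            thr = select_threshold(
                list(zip(p[in_seed], labels[in_seed].astype(bool)))
            )

            dev = ~in_seed
            n_coincident = 0
            if dev.any():
                sup = np.asarray(clf.predict(F[dev])).astype(bool)
                unsup = p[dev] <= thr.threshold
                agree = sup == unsup
                n_coincident = int(agree.sum())
                dev_idx = np.flatnonzero(dev)
                moved = dev_idx[agree]
                labels[moved] = sup[agree].astype(int)
                sources[moved] = "agreed"

            metrics = None
            if eval_F is not None:
                metrics = evaluate_scores(eval_y, _scores(clf, eval_F))
            trace.append(
                IterationRecord(
                    iteration=it,
                    n_coincident=n_coincident,
                    threshold=thr.threshold,
                    seed_size_after=int((labels != -1).sum()),
                    metrics=metrics,
                )
            )
            self.classifier_ = clf
            self.threshold_ = thr.threshold
            if n_coincident == 0:
                break

        self.classes_ = np.array([False, True])
        self.trace_ = trace
        self.n_iter_ = len(trace)
        self.transduction_ = labels
        self.label_sources_ = sources
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        F, _ = self._split_X(X)
        return np.asarray(self.classifier_.predict(F)).astype(bool)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        F, _ = self._split_X(X)
        return self.classifier_.predict_proba(F)

    def decision_scores(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


def _scores(clf, F) -> np.ndarray:
    if hasattr(clf, "decision_scores"):
        return np.asarray(clf.decision_scores(F))
    return np.asarray(clf.predict_proba(F))[:, 1]


# --- labeled-rule-level interface ----------------------------------------


def _stack(rules: Sequence[LabeledRule]) -> tuple[np.ndarray, np.ndarray]:
    """(features+p) design matrix and bool labels for LabeledRule sequences."""
    if len(rules) == 0:
        return np.empty((0, N_FEATURES + 1)), np.empty(0, dtype=bool)
    X = np.vstack(
        [np.append(r.features.to_array(), r.p_value) for r in rules]
    )
    y = np.array([r.label for r in rules])
    return X, y


def split_dataset(
    rules: Sequence[LabeledRule], spec: SplitSpec
) -> tuple[list[LabeledRule], list[LabeledRule]]:
    """Seeded shuffle split into (train, test).

    The test side receives round(test_fraction * n) rules; with
    ``stratified`` the class ratio is preserved within one rule per class.
    """
    if len(rules) < 5:
        raise ValueError("need at least 5 labeled rules to split")
    rng = np.random.default_rng(spec.rng_seed)
    n = len(rules)
    if spec.stratified:
        test_idx: list[int] = []
        for cls in (True, False):
            idx = [i for i, r in enumerate(rules) if r.label is cls]
            k = round(spec.test_fraction * len(idx))
            perm = rng.permutation(len(idx))
            test_idx.extend(idx[j] for j in perm[:k])
        test_set = set(test_idx)
    else:
        k = round(spec.test_fraction * n)
        perm = rng.permutation(n)
        test_set = set(int(i) for i in perm[:k])
    train = [r for i, r in enumerate(rules) if i not in test_set]
    test = [r for i, r in enumerate(rules) if i in test_set]
    return train, test


def sample_seed(
    train: Sequence[LabeledRule], S: int, rng_seed: int
) -> tuple[list[LabeledRule], list[LabeledRule]]:
    """Draw S seed rules uniformly without replacement; rest is development."""
    if not (1 <= S <= len(train)):
        raise ValueError(f"seed size {S} outside [1, {len(train)}]")
    rng = np.random.default_rng(rng_seed)
    chosen = set(int(i) for i in rng.choice(len(train), size=S, replace=False))
    seed = [r for i, r in enumerate(train) if i in chosen]
    development = [r for i, r in enumerate(train) if i not in chosen]
    return seed, development


def run_iteration(
    seed: Sequence[LabeledRule],
    development: Sequence[LabeledRule],
    rng_seed: int = 0,
    base_estimator=None,
) -> tuple[list[LabeledRule], list[LabeledRule], IterationRecord]:
    """One loop step at the labeled-rule level (no test evaluation).

    Development rules' stored labels are not consulted; promoted rules
    carry the agreed prediction with ``label_source="agreed"``.
    """
    if len(seed) == 0:
        raise ValueError("seed must be non-empty")
    clf = ExtraeClassifier(
        base_estimator=base_estimator, max_iter=1, random_state=rng_seed
    )
    X_seed, y_seed = _stack(seed)
    X_dev, _ = _stack(development)
    X = np.vstack([X_seed, X_dev])
    y = np.concatenate([y_seed.astype(int), np.full(len(development), -1)])
    clf.fit(X, y)
    rec = clf.trace_[0]
    new_seed = list(seed)
    new_dev: list[LabeledRule] = []
    for i, r in enumerate(development):
        lab = clf.transduction_[len(seed) + i]
        if lab == -1:
            new_dev.append(r)
        else:
            new_seed.append(
                LabeledRule(r.rule, r.features, r.p_value, bool(lab), "agreed")
            )
    return new_seed, new_dev, rec


def run_extrae(
    rules: Sequence[LabeledRule],
    spec: SplitSpec = SplitSpec(),
    base_estimator=None,
    max_iterations: int = 100,
) -> ExtraeResult:
    """Full pipeline: split, sample seed, iterate to convergence, evaluate.

    Every iteration's model is scored on the held-out test set; the trace
    mirrors the per-iteration evolution table (coincident count, threshold,
    seed size, test metrics).
    """
    train, test = split_dataset(rules, spec)
    if spec.seed_size > len(train):
        raise ValueError("seed_size exceeds the training set")
    seed, development = sample_seed(train, spec.seed_size, spec.rng_seed)

    X_seed, y_seed = _stack(seed)
    X_dev, _ = _stack(development)
    X_test, y_test = _stack(test)
    X = np.vstack([X_seed, X_dev])
    y = np.concatenate([y_seed.astype(int), np.full(len(development), -1)])

    est = ExtraeClassifier(
        base_estimator=base_estimator,
        max_iter=max_iterations,
        random_state=spec.rng_seed,
    )
    est.fit(X, y, eval_set=(X_test, y_test) if len(test) else None)

    ordered = list(seed) + list(development)
    final_seed: list[LabeledRule] = []
    unresolved: list[LabeledRule] = []
    for i, r in enumerate(ordered):
        src = est.label_sources_[i]
        if src == "unresolved":
            unresolved.append(r)
        elif src == "gold":
            final_seed.append(r)
        else:
            final_seed.append(
                LabeledRule(
                    r.rule,
                    r.features,
                    r.p_value,
                    bool(est.transduction_[i]),
                    "agreed",
                )
            )
    final_metrics = est.trace_[-1].metrics if est.trace_ else None
    return ExtraeResult(
        trace=est.trace_,
        final_model=est.classifier_,
        final_seed=final_seed,
        unresolved=unresolved,
        test=list(test),
        final_metrics=final_metrics,
    )
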