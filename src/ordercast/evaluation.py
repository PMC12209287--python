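"""Splitting, training and evaluation primitives.

Thin, well-specified wrappers around scikit-learn: a stratified 70/30
split, a balanced random forest, the standard binary metric suite
(positive class = entire acceptance), stratified k-fold indices, Gini
importances and the four-variable Pearson correlation table.

All randomness is derived from a single integer seed; named sub-streams
(split / train / cv / synth) come from :func:`subseed`, so fixing the
top-level seed fixes every stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence
from zlib import crc32

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .exceptions import OrdercastError

logger = logging.getLogger(__name__)

#: Variables eligible for the bivariate Pearson table: the numeric,
#: monotone predictors only.
CORRELATION_VARIABLES = ("expanded_score", "burden_score",
                         "time_requested", "time_granted")


def subseed(seed: int, name: str) -> int:
    """Deterministic named sub-seed in [0, 2^31) derived from the
    top-level seed."""
    ss = np.random.SeedSequence([int(seed), crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = entire acceptance."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """2x2 array in scikit-learn layout [[tn, fp], [fn, tp]]."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def compute_metrics(pred: Sequence[int], truth: Sequence[int],
                    ) -> tuple[ConfusionMatrix, Metrics]:
    """Confusion matrix and accuracy/precision/recall/F1.

    Precision and recall with a zero denominator are reported as 0 (and
    logged) rather than NaN, so downstream reports stay numeric.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise OrdercastError(
            f"prediction/truth length mismatch: {pred.shape} vs {truth.shape}")
    if not (set(np.unique(pred)) <= {0, 1} and set(np.unique(truth)) <= {0, 1}):
        raise OrdercastError("labels must be binary 0/1")
    tn, fp, fn, tp = _sk_confusion(truth, pred, labels=[0, 1]).ravel()
    cm = ConfusionMatrix(tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn))
    accuracy = (tp + tn) / cm.total if cm.total else 0.0
    if tp + fp == 0:
        logger.warning("precision undefined (no positive predictions); using 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("recall undefined (no positive truths); using 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return cm, Metrics(accuracy=float(accuracy), precision=float(precision),
                       recall=float(recall), f1=float(f1))


def split_train_test(items: Sequence, labels: Sequence[int],
                     test_fraction: float = 0.30, seed: int = 0,
                     ) -> tuple[list, list, np.ndarray, np.ndarray]:
    """Stratified train/test split of arbitrary items.

    Per-class test counts are allocated by largest remainder against a
    total of ``round(test_fraction * n)``, which keeps every class's
    test share within one case of ``test_fraction`` exactly.  Returns
    (train_items, test_items, train_labels, test_labels); deterministic
    given the seed.
    """
    labels = np.asarray(labels, dtype=int)
    if not 0 < test_fraction < 1:
        raise OrdercastError(f"test_fraction={test_fraction} outside (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise OrdercastError("cannot split single-class data with stratification")
    if counts.min() < 2:
        raise OrdercastError("need at least 2 cases per outcome class to split")
    n_test_total = int(round(test_fraction * len(labels)))
    n_test_total = min(max(n_test_total, 1), len(labels) - 1)
    targets = {c: test_fraction * n_c for c, n_c in zip(classes, counts)}
    take = {c: int(np.floor(targets[c])) for c in classes}
    # distribute the remaining test slots by descending fractional part
    leftover = n_test_total - sum(take.values())
    order = sorted(classes, key=lambda c: (-(targets[c] - take[c]), c))
    for c in order[:max(leftover, 0)]:
        take[c] += 1
    rng = np.random.default_rng(subseed(seed, "split"))
    te_parts = []
    for c, n_c in zip(classes, counts):
        take[c] = min(max(take[c], 1), n_c - 1)  # both splits see each class
        cls_idx = np.flatnonzero(labels == c)
        te_parts.append(rng.permutation(cls_idx)[:take[c]])
    te = np.sort(np.concatenate(te_parts))
    tr = np.setdiff1d(np.arange(len(labels)), te)
    return ([items[i] for i in tr], [items[i] for i in te],
            labels[tr], labels[te])


def train_forest(X: np.ndarray, y: Sequence[int], seed: int = 0,
                 n_trees: int = 100) -> RandomForestClassifier:
    """Fit the balanced random forest (inverse-class-frequency sample
    weighting via ``class_weight='balanced'``)."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise OrdercastError("degenerate labels: need both outcome classes "
                             "to train")
    clf = RandomForestClassifier(n_estimators=n_trees,
                                 class_weight="balanced",
                                 random_state=subseed(seed, "train"))
    clf.fit(X, y)
    return clf


def stratified_folds(labels: Sequence[int], n_splits: int = 10,
                     seed: int = 0) -> list[np.ndarray]:
    """Validation-fold index arrays of a stratified k-fold partition."""
    labels = np.asarray(labels, dtype=int)
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2 or counts.min() < n_splits:
        raise OrdercastError(
            f"class too small to stratify into {n_splits} folds "
            f"(class counts: {counts.tolist()})")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=subseed(seed, "cv"))
    return [val for _, val in skf.split(np.zeros(len(labels)), labels)]


def feature_importances(model: RandomForestClassifier,
                        feature_names: Sequence[str]) -> dict[str, float]:
    """Normalized mean-decrease-in-Gini importances, sorted descending
    (ties broken by feature name)."""
    if not hasattr(model, "feature_importances_"):
        raise OrdercastError("model is not trained; no importances available")
    imp = model.feature_importances_
    if len(imp) != len(feature_names):
        raise OrdercastError("feature-name list does not match the model")
    pairs = sorted(zip(feature_names, imp), key=lambda p: (-p[1], p[0]))
    return {name: float(v) for name, v in pairs}


def correlation_table(features: pd.DataFrame,
                      variables: Sequence[str] = CORRELATION_VARIABLES,
                      ) -> pd.DataFrame:
    """Pairwise Pearson correlations among the designated numeric
    variables.

    Entries involving a constant column are NaN (undefined), never 0.
    """
    missing = [v for v in variables if v not in features.columns]
    if missing:
        raise OrdercastError(f"missing correlation variable(s): {missing}")
    if len(features) < 3:
        raise OrdercastError("need at least 3 cases for a correlation table")
    sub = features.loc[:, list(variables)].astype(float)
    return sub.corr(method="pearson")
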