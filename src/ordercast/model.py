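"""The hybrid fuzzy + random-forest model, statsmodels-style.

:class:`TreatmentOrderModel` is built from judgment records (or a CSV
file in the canonical schema); :meth:`~TreatmentOrderModel.fit` runs
the full pipeline — semantic flags, training-split min–max scalers,
Burden_Score, fuzzy Expanded_Score, stratified 70/30 split, balanced
random forest — and returns a :class:`TreatmentOrderResults` carrying
the held-out metrics, confusion matrix, Gini importances, the Pearson
correlation table and a ``summary()`` text report.

Example
-------
>>> from ordercast import TreatmentOrderModel, GeneratorConfig, generate_records
>>> records = generate_records(GeneratorConfig(n=200, seed=7))
>>> res = TreatmentOrderModel.from_records(records).fit(seed=7)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

from .evaluation import (
    ConfusionMatrix,
    Metrics,
    compute_metrics,
    correlation_table,
    feature_importances,
    split_train_test,
    stratified_folds,
    subseed,
    train_forest,
)
from .exceptions import OrdercastError
from .features import DEFAULT_BURDEN_WEIGHTS, FEATURE_NAMES, BurdenWeights
from .fuzzy import FuzzyConfig
from .lexicon import Lexicon
from .pipeline import analyse_record, featurize, fit_scalers, outcome_labels
from .records import JudgmentRecord, filter_modellable, read_records


class TreatmentOrderModel:
    """Hybrid model of entire-vs-partial treatment-order acceptance.

    Parameters
    ----------
    records
        Modellable judgment records (accepted, entire or partial).
        Use :meth:`from_records` / :meth:`from_csv` to filter raw input.
    lexicon, fuzzy_config, burden_weights
        Pipeline configuration; defaults reproduce the reference system.
    exclude_time_granted
        Drop the court-granted duration from the classifier features
        (it is determined alongside the outcome, so including it —
        the default, and the reference behaviour — is a deliberate
        leakage trade-off).
    """

    def __init__(self, records: Sequence[JudgmentRecord], *,
                 lexicon: Lexicon | None = None,
                 fuzzy_config: FuzzyConfig | None = None,
                 burden_weights: BurdenWeights = DEFAULT_BURDEN_WEIGHTS,
                 exclude_time_granted: bool = False):
        if not records:
            raise OrdercastError("no records supplied")
        self.records = list(records)
        self.lexicon = lexicon or Lexicon()
        self.fuzzy_config = fuzzy_config or FuzzyConfig()
        self.burden_weights = burden_weights
        self.exclude_time_granted = exclude_time_granted
        self.endog = outcome_labels(self.records)
        if len(np.unique(self.endog)) < 2:
            raise OrdercastError("need both entire and partial outcomes "
                                 "to model")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[JudgmentRecord],
                     **kwargs) -> "TreatmentOrderModel":
        """Build from raw records, keeping only modellable cases."""
        return cls(filter_modellable(records), **kwargs)

    @classmethod
    def from_csv(cls, path, header_map: Mapping[str, str] | None = None,
                 **kwargs) -> "TreatmentOrderModel":
        """Read a canonical-schema CSV file and build from its
        modellable cases."""
        return cls.from_records(read_records(path, header_map=header_map),
                                **kwargs)

    # -- helpers ------------------------------------------------------------

    @property
    def feature_names(self) -> list[str]:
        names = list(FEATURE_NAMES)
        if self.exclude_time_granted:
            names.remove("time_granted")
        return names

    def _features(self, records: Sequence[JudgmentRecord],
                  scalers: Mapping[str, tuple[float, float]]) -> pd.DataFrame:
        df = featurize(records, self.lexicon, self.fuzzy_config, scalers,
                       self.burden_weights)
        return df

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        return features.loc[:, self.feature_names].to_numpy(dtype=float)

    # -- estimation ---------------------------------------------------------

    def fit(self, test_fraction: float = 0.30, n_trees: int = 100,
            seed: int = 0) -> "TreatmentOrderResults":
        """Split, build features, train the forest, evaluate held-out.

        Deterministic given ``seed``: the split, the forest and every
        reported number are reproduced exactly on re-run.
        """
        train_recs, test_recs, y_train, y_test = split_train_test(
            self.records, self.endog, test_fraction=test_fraction, seed=seed)
        scalers = fit_scalers(train_recs)
        train_feats = self._features(train_recs, scalers)
        test_feats = self._features(test_recs, scalers)
        clf = train_forest(self._matrix(train_feats), y_train, seed=seed,
                           n_trees=n_trees)
        y_pred = _predict_labels(clf, self._matrix(test_feats))
        proba = clf.predict_proba(self._matrix(test_feats))
        cm, metrics = compute_metrics(y_pred, y_test)
        all_feats = self._features(self.records, scalers)
        return TreatmentOrderResults(
            model=self, estimator=clf, scalers=dict(scalers),
            seed=seed, test_fraction=test_fraction, n_trees=n_trees,
            train_features=train_feats, test_features=test_feats,
            y_train=y_train, y_test=y_test, y_pred=y_pred,
            test_proba=proba, confusion=cm, metrics=metrics,
            importances=feature_importances(clf, self.feature_names),
            correlations=correlation_table(all_feats),
        )

    def cross_validate(self, n_splits: int = 10, n_trees: int = 100,
                       seed: int = 0) -> "CrossValidationResults":
        """Stratified k-fold cross-validation of the whole pipeline.

        Scalers are refitted on each training fold so no information
        leaks from a validation fold into its features.
        """
        folds = stratified_folds(self.endog, n_splits=n_splits, seed=seed)
        per_fold: list[Metrics] = []
        for k, val_idx in enumerate(folds):
            val_mask = np.zeros(len(self.records), dtype=bool)
            val_mask[val_idx] = True
            train_recs = [r for r, m in zip(self.records, val_mask) if not m]
            val_recs = [r for r, m in zip(self.records, val_mask) if m]
            scalers = fit_scalers(train_recs)
            clf = train_forest(
                self._matrix(self._features(train_recs, scalers)),
                self.endog[~val_mask], seed=subseed(seed, f"fold{k}"),
                n_trees=n_trees)
            pred = _predict_labels(
                clf, self._matrix(self._features(val_recs, scalers)))
            _, m = compute_metrics(pred, self.endog[val_mask])
            per_fold.append(m)
        return CrossValidationResults(per_fold=per_fold, folds=folds,
                                      n_splits=n_splits, seed=seed)


def _predict_labels(clf, X: np.ndarray) -> np.ndarray:
    """Argmax of predict_proba with ties broken toward the positive
    class."""
    proba = clf.predict_proba(X)
    pos = list(clf.classes_).index(1)
    return (proba[:, pos] >= 0.5).astype(int)


@dataclass
class TreatmentOrderResults:
    """Fit results: held-out evaluation, importances, correlations, and
    prediction/tracing on new records."""

    model: TreatmentOrderModel
    estimator: object
    scalers: dict[str, tuple[float, float]]
    seed: int
    test_fraction: float
    n_trees: int
    train_features: pd.DataFrame
    test_features: pd.DataFrame
    y_train: np.ndarray
    y_test: np.ndarray
    y_pred: np.ndarray
    test_proba: np.ndarray
    confusion: ConfusionMatrix
    metrics: Metrics
    importances: dict[str, float]
    correlations: pd.DataFrame

    # -- prediction ---------------------------------------------------------

    def _matrix_for(self, records: Sequence[JudgmentRecord]) -> np.ndarray:
        feats = featurize(records, self.model.lexicon, self.model.fuzzy_config,
                          self.scalers, self.model.burden_weights)
        return feats.loc[:, self.model.feature_names].to_numpy(dtype=float)

    def predict(self, records: Sequence[JudgmentRecord]) -> np.ndarray:
        """Predicted outcome (1 = entire acceptance) for new records."""
        return _predict_labels(self.estimator, self._matrix_for(records))

    def predict_proba(self, records: Sequence[JudgmentRecord]) -> np.ndarray:
        """Class-probability rows (columns ordered partial, entire)."""
        return self.estimator.predict_proba(self._matrix_for(records))

    def predict_matrix(self, X: np.ndarray,
                       feature_names: Sequence[str]) -> np.ndarray:
        """Predict from a pre-built matrix; errors on feature-order
        mismatch."""
        if list(feature_names) != self.model.feature_names:
            raise OrdercastError(
                f"feature order mismatch: expected {self.model.feature_names}, "
                f"got {list(feature_names)}")
        return _predict_labels(self.estimator, np.asarray(X, dtype=float))

    def trace(self, record: JudgmentRecord) -> dict:
        """Per-case explanation: flags, burden decomposition, fired
        rules, fuzzy score/category, predicted label and probability."""
        info = analyse_record(record, self.model.lexicon,
                              self.model.fuzzy_config, self.scalers,
                              self.model.burden_weights)
        proba = self.predict_proba([record])[0]
        pos = list(self.estimator.classes_).index(1)
        info["predicted_label"] = int(proba[pos] >= 0.5)
        info["probability_entire"] = float(proba[pos])
        return info

    # -- reporting ----------------------------------------------------------

    def to_report(self) -> dict:
        """JSON-serializable evaluation report (deterministic given the
        fit seed)."""
        cm = self.confusion
        return {
            "n_cases": len(self.model.records),
            "n_train": len(self.y_train),
            "n_test": len(self.y_test),
            "test_fraction": self.test_fraction,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "feature_names": self.model.feature_names,
            "scalers": {k: list(v) for k, v in self.scalers.items()},
            "metrics": self.metrics.as_dict(),
            "confusion_matrix": {"tp": cm.tp, "fp": cm.fp,
                                 "fn": cm.fn, "tn": cm.tn},
            "feature_importances": self.importances,
            "correlations": {
                a: {b: (None if pd.isna(v) else round(float(v), 6))
                    for b, v in row.items()}
                for a, row in self.correlations.iterrows()},
        }

    def save(self, path) -> None:
        """Persist the full bundle (forest, scalers, lexicon, fuzzy
        config, feature order, seeds) to one file."""
        payload = {
            "estimator": self.estimator,
            "scalers": self.scalers,
            "lexicon": self.model.lexicon,
            "fuzzy_config_dict": self.model.fuzzy_config.to_dict(),
            "burden_weights": self.model.burden_weights,
            "exclude_time_granted": self.model.exclude_time_granted,
            "feature_names": self.model.feature_names,
            "results": self,
        }
        joblib.dump(payload, path)

    @staticmethod
    def load(path) -> "TreatmentOrderResults":
        payload = joblib.load(path)
        return payload["results"]

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels idiom."""
        cm = self.confusion
        lines = [
            "Hybrid fuzzy + random-forest treatment-order model",
            "=" * 56,
            f"No. cases:       {len(self.model.records):>6}"
            f"    entire: {int(self.model.endog.sum())}"
            f"  partial: {int((1 - self.model.endog).sum())}",
            f"Train / test:    {len(self.y_train):>6} / {len(self.y_test)}"
            f"    (test fraction {self.test_fraction:.2f}, seed {self.seed})",
            f"Forest:          {self.n_trees} trees, class_weight=balanced",
            "-" * 56,
            "Held-out performance (positive class = entire acceptance)",
            f"  accuracy   {self.metrics.accuracy:7.3f}",
            f"  precision  {self.metrics.precision:7.3f}",
            f"  recall     {self.metrics.recall:7.3f}",
            f"  F1         {self.metrics.f1:7.3f}",
            f"  confusion  tp={cm.tp} fp={cm.fp} fn={cm.fn} tn={cm.tn}",
            "-" * 56,
            "Gini feature importances",
        ]
        for name, v in self.importances.items():
            lines.append(f"  {name:<16} {v:7.3f}")
        lines.append("-" * 56)
        lines.append("Pearson correlations (numeric monotone predictors)")
        lines.append(self.correlations.round(3).to_string())
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_confusion(self, ax=None):
        """Heatmap of the held-out confusion matrix."""
        from .plotting import plot_confusion
        return plot_confusion(self.confusion, ax=ax)

    def plot_correlations(self, ax=None):
        """Heatmap of the Pearson correlation table."""
        from .plotting import plot_correlations
        return plot_correlations(self.correlations, ax=ax)


@dataclass
class CrossValidationResults:
    """Per-fold metrics of a stratified k-fold run, with mean and SD."""

    per_fold: list[Metrics]
    folds: list[np.ndarray]
    n_splits: int
    seed: int

    def mean(self) -> dict[str, float]:
        return {k: float(np.mean([m.as_dict()[k] for m in self.per_fold]))
                for k in ("accuracy", "precision", "recall", "f1")}

    def std(self) -> dict[str, float]:
        return {k: float(np.std([m.as_dict()[k] for m in self.per_fold]))
                for k in ("accuracy", "precision", "recall", "f1")}

    def to_report(self) -> dict:
        return {"n_splits": self.n_splits, "seed": self.seed,
                "per_fold": [m.as_dict() for m in self.per_fold],
                "mean": self.mean(), "std": self.std()}

    def summary(self) -> str:
        mean, std = self.mean(), self.std()
        lines = [f"{self.n_splits}-fold stratified cross-validation "
                 f"(seed {self.seed})"]
        for k in ("accuracy", "precision", "recall", "f1"):
            lines.append(f"  {k:<10} {mean[k]:.3f} +/- {std[k]:.3f}")
        return "\n".join(lines)
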