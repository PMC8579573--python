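"""Combined feature matrices and the trainable hexapeptide classifier.

The classifier is a scikit-learn-style estimator: ``fit`` takes an
iterable of amino-acid sequences (or ``PeptideRecord``) plus binary
labels, encodes each sample as PseAAC block + selected-tripeptide TPC
block, and trains a pluggable learner (random forest by default, 500
trees). ``predict_proba`` returns positive-class probabilities; the
binary call uses a configurable decision threshold (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .encoders import PseAACParams, pseaac_feature_names, pseaac_vector, tpc_vector
from .io import PeptideRecord
from .metrics import ConfusionCounts, compute_metrics, roc_auc
from .selection import (FeatureSpec, confidence_levels, count_tripeptides,
                        rank_and_select)

MODEL_FORMAT_VERSION = 1

# Pluggable classifier registry: name -> factory(n_trees, seed) -> estimator
# with fit / predict_proba. Alternatives (SVM, boosting, ...) register here.
CLASSIFIERS: dict[str, Callable[[int, int], BaseEstimator]] = {}


def register_classifier(name: str, factory: Callable[[int, int], BaseEstimator]) -> None:
    CLASSIFIERS[name] = factory


register_classifier(
    "random_forest",
    lambda n_trees, seed: RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    ),
)


@dataclass
class TrainingConfig:
    """Training/cross-validation settings."""

    classifier_name: str = "random_forest"
    n_trees: int = 500
    seed: int = 0
    decision_threshold: float = 0.5
    folds: int = 10

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0,1)")


def _sequences_of(dataset: Sequence) -> list[str]:
    return [r.sequence if hasattr(r, "sequence") else str(r) for r in dataset]


def feature_names(spec: FeatureSpec) -> list[str]:
    return pseaac_feature_names(spec.pseaac_params) + [
        f"tpc_{t}" for t in spec.selected_tripeptides
    ]


def build_feature_matrix(dataset: Sequence, spec: FeatureSpec):
    """Encode a dataset under a feature spec.

    Returns ``(X, y, names)``: X of shape (n, spec.total_dim) as a
    DataFrame with stable column names, y the label vector (None entries
    allowed for unlabeled data), names the column list.
    """
    seqs = _sequences_of(dataset)
    params = spec.pseaac_params
    sel = spec.selected_indices()
    rows = []
    for rec, seq in zip(dataset, seqs):
        try:
            pse = pseaac_vector(seq, params)
            tpc = tpc_vector(seq)[sel] if sel.size else np.empty(0)
        except ValueError as exc:
            rid = getattr(rec, "id", seq)
            raise ValueError(f"cannot encode record {rid!r}: {exc}") from exc
        rows.append(np.concatenate([pse, tpc]))
    names = feature_names(spec)
    X = pd.DataFrame(np.stack(rows) if rows else np.empty((0, spec.total_dim)),
                     columns=names)
    labels = [getattr(r, "label", None) for r in dataset]
    y = np.array([l if l is not None else -1 for l in labels]) \
        if any(l is not None for l in labels) else None
    return X, y, names


class AmyloidClassifier(ClassifierMixin, BaseEstimator):
    """Amyloidogenicity classifier over short peptides.

    Combines a Type 2 PseAAC block with binomially selected tripeptide
    frequencies and a random forest (or any registered learner).

    Parameters
    ----------
    feature_spec : FeatureSpec or None
        A pre-computed feature layout. When None, tripeptide selection is
        performed on the training data during ``fit`` using ``select_mode``
        / ``select_value``.
    select_mode, select_value : selection rule when feature_spec is None
        (CL threshold 0.85 by default, or ``top_k`` with an integer).
    lambda_rank, weight, count_mode : PseAAC parameters (defaults 2 / 0.7 /
        raw counts), ignored when ``feature_spec`` is given.
    classifier_name, n_trees, random_state : learner configuration.
    decision_threshold : probability cutoff for the binary call.

    Attributes
    ----------
    feature_spec_ : the feature layout actually used.
    estimator_ : the fitted underlying learner.
    stats_ : tripeptide statistics (only when selection ran during fit).
    classes_ : ndarray [0, 1].
    """

    def __init__(self, feature_spec: FeatureSpec | None = None,
                 select_mode: str = "threshold", select_value: float | int = 0.85,
                 lambda_rank: int = 2, weight: float = 0.7,
                 count_mode: str = "count",
                 classifier_name: str = "random_forest", n_trees: int = 500,
                 random_state: int = 0, decision_threshold: float = 0.5):
        self.feature_spec = feature_spec
        self.select_mode = select_mode
        self.select_value = select_value
        self.lambda_rank = lambda_rank
        self.weight = weight
        self.count_mode = count_mode
        self.classifier_name = classifier_name
        self.n_trees = n_trees
        self.random_state = random_state
        self.decision_threshold = decision_threshold

    def _pseaac_params(self) -> PseAACParams:
        return PseAACParams(lambda_rank=self.lambda_rank, weight=self.weight,
                            count_mode=self.count_mode)  # type: ignore[arg-type]

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        if not set(classes) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        records = [
            x if isinstance(x, PeptideRecord)
            else PeptideRecord(id=f"s{i}", sequence=str(x))
            for i, x in enumerate(X)
        ]
        for rec, label in zip(records, y):
            rec.label = int(label)
        if self.feature_spec is not None:
            self.feature_spec_ = self.feature_spec
        else:
            counts_table = count_tripeptides(records)
            self.stats_ = confidence_levels(counts_table)
            self.feature_spec_ = rank_and_select(
                self.stats_, self.select_mode, self.select_value,  # type: ignore[arg-type]
                pseaac_params=self._pseaac_params())
        if self.classifier_name not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier_name!r}")
        Xm, _, _ = build_feature_matrix(records, self.feature_spec_)
        est = CLASSIFIERS[self.classifier_name](self.n_trees, self.random_state)
        est.fit(Xm.to_numpy(), y)
        self.estimator_ = est
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.feature_spec_.total_dim
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Positive-class probability per sample."""
        check_is_fitted(self, "estimator_")
        Xm, _, _ = build_feature_matrix(list(X), self.feature_spec_)
        proba = self.estimator_.predict_proba(Xm.to_numpy())
        pos_col = int(np.where(self.estimator_.classes_ == 1)[0][0])
        return proba[:, pos_col]

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_scores(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.decision_threshold).astype(int)


@dataclass
class TrainedModel:
    """A fitted classifier plus the feature layout and config that produced it."""

    feature_spec: FeatureSpec
    config: TrainingConfig
    classifier: AmyloidClassifier
    training_summary: dict = field(default_factory=dict)

    def predict_proba(self, records: Sequence) -> np.ndarray:
        return self.classifier.decision_scores(records)

    def predict(self, records: Sequence) -> np.ndarray:
        return (self.predict_proba(records) >= self.config.decision_threshold).astype(int)


def train(dataset: Sequence[PeptideRecord], spec: FeatureSpec,
          config: TrainingConfig | None = None) -> TrainedModel:
    """Train the configured classifier on a labeled dataset under a feature spec."""
    config = config or TrainingConfig()
    clf = AmyloidClassifier(
        feature_spec=spec, classifier_name=config.classifier_name,
        n_trees=config.n_trees, random_state=config.seed,
        decision_threshold=config.decision_threshold)
    y = np.array([r.label for r in dataset])
    clf.fit(dataset, y)
    summary = {"n_samples": len(dataset), "n_pos": int((y == 1).sum()),
               "n_neg": int((y == 0).sum()), "total_dim": spec.total_dim,
               "config": asdict(config)}
    return TrainedModel(feature_spec=spec, config=config, classifier=clf,
                        training_summary=summary)


def predict_proba(model: TrainedModel, records: Sequence) -> np.ndarray:
    """Per-record amyloidogenicity score in [0, 1]."""
    return model.predict_proba(records)


def cross_validate(dataset: Sequence[PeptideRecord], spec: FeatureSpec,
                   config: TrainingConfig | None = None) -> dict:
    """Stratified k-fold cross-validation with pooled out-of-fold metrics.

    Fold assignment is deterministic given ``config.seed``. Pooled metrics
    (ACC, SE, SP, Q, MCC, AUC) are computed on the concatenated
    out-of-fold predictions; per-fold metrics are also returned.
    """
    config = config or TrainingConfig()
    y = np.array([r.label for r in dataset])
    if y.min() == y.max():
        raise ValueError("cross-validation needs both classes")
    class_sizes = np.bincount(y)
    if config.folds > class_sizes[class_sizes > 0].min():
        raise ValueError("folds exceed the smaller class size")
    X, _, _ = build_feature_matrix(dataset, spec)
    Xa = X.to_numpy()
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    oof_scores = np.empty(len(y))
    fold_rows = []
    for fold, (tr, te) in enumerate(skf.split(Xa, y)):
        est = CLASSIFIERS[config.classifier_name](config.n_trees, config.seed)
        est.fit(Xa[tr], y[tr])
        pos_col = int(np.where(est.classes_ == 1)[0][0])
        scores = est.predict_proba(Xa[te])[:, pos_col]
        oof_scores[te] = scores
        calls = (scores >= config.decision_threshold).astype(int)
        c = ConfusionCounts(
            tp=int(((calls == 1) & (y[te] == 1)).sum()),
            fp=int(((calls == 1) & (y[te] == 0)).sum()),
            tn=int(((calls == 0) & (y[te] == 0)).sum()),
            fn=int(((calls == 0) & (y[te] == 1)).sum()),
        )
        m = compute_metrics(c)
        fold_rows.append({"fold": fold, "acc": m.acc, "se": m.se, "sp": m.sp,
                          "q": m.q, "mcc": m.mcc})
    calls = (oof_scores >= config.decision_threshold).astype(int)
    pooled_c = ConfusionCounts(
        tp=int(((calls == 1) & (y == 1)).sum()),
        fp=int(((calls == 1) & (y == 0)).sum()),
        tn=int(((calls == 0) & (y == 0)).sum()),
        fn=int(((calls == 0) & (y == 1)).sum()),
    )
    pooled = compute_metrics(pooled_c)
    auc, _ = roc_auc(oof_scores, y)
    return {
        "pooled": {"acc": pooled.acc, "se": pooled.se, "sp": pooled.sp,
                   "q": pooled.q, "mcc": pooled.mcc, "auc": auc},
        "folds": pd.DataFrame(fold_rows),
        "oof_scores": oof_scores,
        "confusion": pooled_c,
    }


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model (feature spec + config + learner) to one file."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return payload["model"]
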