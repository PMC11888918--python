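"""Stacking ensemble classifier over MC features.

Four heterogeneous base learners — XGBoost, k-nearest neighbors, random
forest and Gaussian naive Bayes — are each evaluated with stratified
k-fold out-of-fold prediction on the training set; their predicted class
probabilities (not hard labels) form the meta-feature matrix on which a
multinomial logistic-regression fuser is trained.  The base learners are
then refit on the full training set.  Out-of-fold meta-features are what
keeps the fuser honest: a label-shuffle control must land at chance.

Defaults: XGBoost with 100 trees at learning rate 0.01, KNN with k=100,
random forest with 80 trees of depth 5 (min 1 sample per leaf, min 2 to
split), 5 internal folds.  KNN's k must be smaller than every internal
training fold; small benchmarks therefore need a smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import LabelEncoder
from xgboost import XGBClassifier

from .evaluate import MetricsReport, confusion, metrics
from .features import apply_normalizer, fit_normalizer

BASE_LEARNER_NAMES = ("xgb", "knn", "rf", "nb")


@dataclass
class StackingConfig:
    xgb_n_estimators: int = 100
    xgb_learning_rate: float = 0.01
    knn_k: int = 100
    rf_n_trees: int = 80
    rf_max_depth: int = 5
    min_samples_leaf: int = 1
    min_samples_split: int = 2
    meta_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "xgb_n_estimators",
            "knn_k",
            "rf_n_trees",
            "rf_max_depth",
            "min_samples_leaf",
            "min_samples_split",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.meta_folds < 2:
            raise ValueError("meta_folds must be >= 2")
        if self.xgb_learning_rate <= 0:
            raise ValueError("xgb_learning_rate must be positive")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def make_base_learners(config: StackingConfig) -> dict:
    """Fresh, unfitted base learners keyed by short name."""
    return {
        "xgb": XGBClassifier(
            n_estimators=config.xgb_n_estimators,
            learning_rate=config.xgb_learning_rate,
            random_state=config.seed,
            verbosity=0,
            n_jobs=1,
            eval_metric="mlogloss",
        ),
        "knn": KNeighborsClassifier(n_neighbors=config.knn_k, n_jobs=1),
        "rf": RandomForestClassifier(
            n_estimators=config.rf_n_trees,
            max_depth=config.rf_max_depth,
            min_samples_leaf=config.min_samples_leaf,
            min_samples_split=config.min_samples_split,
            random_state=config.seed,
            n_jobs=1,
        ),
        "nb": GaussianNB(),
    }


@dataclass
class FittedStack:
    base_learners: dict
    fuser: LogisticRegression
    label_encoder: LabelEncoder
    config: StackingConfig
    n_features: int

    @property
    def classes_(self) -> np.ndarray:
        return self.label_encoder.classes_

    def _check(self, features) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match fitted "
                f"{self.n_features}"
            )
        return x

    def predict_proba(self, features) -> np.ndarray:
        x = self._check(features)
        meta = np.hstack(
            [self.base_learners[n].predict_proba(x) for n in BASE_LEARNER_NAMES]
        )
        return self.fuser.predict_proba(meta)

    def predict(self, features) -> np.ndarray:
        proba = self.predict_proba(features)
        return self.label_encoder.inverse_transform(np.argmax(proba, axis=1))


def _oof_probabilities(estimator, x, y_enc, n_classes, skf) -> np.ndarray:
    """Out-of-fold class probabilities with globally consistent columns."""
    oof = np.zeros((len(y_enc), n_classes))
    for tr, te in skf.split(x, y_enc):
        if len(np.unique(y_enc[tr])) < n_classes:
            raise ValueError(
                "a class is missing from an internal training fold; "
                "provide more samples per class or fewer meta_folds"
            )
        est = clone(estimator)
        est.fit(x[tr], y_enc[tr])
        proba = est.predict_proba(x[te])
        cols = np.asarray(est.classes_, dtype=int)
        oof[np.ix_(te, cols)] = proba
    return oof


def fit_stacking(features, labels, config: StackingConfig | None = None) -> FittedStack:
    """Train the stacking ensemble with out-of-fold meta-features."""
    config = config or StackingConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be S x D with one label per row")
    le = LabelEncoder()
    y_enc = le.fit_transform(y)
    n_classes = len(le.classes_)
    if len(x) < config.meta_folds * n_classes:
        raise ValueError(
            "too few samples to stratify: need at least meta_folds * n_classes"
        )
    min_fold_train = min(
        len(tr)
        for tr, _ in StratifiedKFold(
            config.meta_folds, shuffle=True, random_state=config.seed
        ).split(x, y_enc)
    )
    if config.knn_k >= min_fold_train:
        raise ValueError(
            f"knn_k={config.knn_k} must be smaller than the smallest internal "
            f"training fold ({min_fold_train} samples); lower knn_k"
        )
    skf = StratifiedKFold(config.meta_folds, shuffle=True, random_state=config.seed)
    bases = make_base_learners(config)
    meta = np.hstack(
        [
            _oof_probabilities(bases[n], x, y_enc, n_classes, skf)
            for n in BASE_LEARNER_NAMES
        ]
    )
    fuser = LogisticRegression(max_iter=2000, random_state=config.seed)
    fuser.fit(meta, y_enc)
    for n in BASE_LEARNER_NAMES:
        bases[n].fit(x, y_enc)
    return FittedStack(bases, fuser, le, config, x.shape[1])


def predict(stack: FittedStack, features):
    """Labels and class probabilities for a feature batch."""
    return stack.predict(features), stack.predict_proba(features)


def mean_report(reports: list[MetricsReport]) -> dict:
    """Across-fold mean of the scalar metrics."""
    return {
        "accuracy": float(np.mean([r.accuracy for r in reports])),
        "precision": float(np.mean([r.precision_macro for r in reports])),
        "recall": float(np.mean([r.recall_macro for r in reports])),
        "f1": float(np.mean([r.f1_macro for r in reports])),
        "mcc": float(np.mean([r.mcc for r in reports])),
        "n_folds": len(reports),
    }


def cross_validate(
    features,
    labels,
    config: StackingConfig | None = None,
    n_folds: int = 5,
    normalize: bool = True,
) -> tuple[list[MetricsReport], dict]:
    """Stratified k-fold evaluation of the stack, leak-free.

    Feature normalization and the whole stacking fit happen inside each
    training fold only; the held-out fold is transformed with the training
    fold's statistics.
    """
    config = config or StackingConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify "
            f"{n_folds} folds"
        )
    skf = StratifiedKFold(n_folds, shuffle=True, random_state=config.seed)
    reports = []
    for tr, te in skf.split(x, y):
        x_tr, x_te = x[tr], x[te]
        if normalize:
            stats = fit_normalizer(x_tr)
            x_tr = apply_normalizer(x_tr, stats)
            x_te = apply_normalizer(x_te, stats)
        stack = fit_stacking(x_tr, y[tr], config)
        pred = stack.predict(x_te)
        reports.append(metrics(confusion(y[te], pred)))
    return reports, mean_report(reports)


def cross_validate_single(
    features,
    labels,
    estimator_name: str,
    config: StackingConfig | None = None,
    n_folds: int = 5,
    normalize: bool = True,
) -> tuple[list[MetricsReport], dict]:
    """Same protocol for one base learner alone (for stack-vs-base comparisons)."""
    config = config or StackingConfig()
    if estimator_name not in BASE_LEARNER_NAMES:
        raise ValueError(f"estimator_name must be one of {BASE_LEARNER_NAMES}")
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    le = LabelEncoder()
    y_enc = le.fit_transform(y)
    skf = StratifiedKFold(n_folds, shuffle=True, random_state=config.seed)
    reports = []
    for tr, te in skf.split(x, y_enc):
        x_tr, x_te = x[tr], x[te]
        if normalize:
            stats = fit_normalizer(x_tr)
            x_tr = apply_normalizer(x_tr, stats)
            x_te = apply_normalizer(x_te, stats)
        est = make_base_learners(config)[estimator_name]
        est.fit(x_tr, y_enc[tr])
        pred = le.inverse_transform(est.predict(x_te))
        reports.append(metrics(confusion(y[te], pred)))
    return reports, mean_report(reports)
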