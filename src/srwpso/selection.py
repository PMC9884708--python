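"""bSRWPSO-FKNN wrapper feature selection.

A binary swarm searches over feature masks; a mask's fitness combines the
FKNN misclassification rate on the masked features with a subset-size
penalty,

    Fitness = alpha * Error + (1 - alpha) * R / D,    alpha = 0.99,

so error dominates and, among equally accurate subsets, smaller ones win.
The empty mask receives the sentinel fitness 1.0 (the worst achievable
value) and is therefore never selected.

Evaluation is leakage-free: for every outer cross-validation fold the
min-max scaler, the inner fitness hold-out and the swarm search see only
the outer-training rows; the reported metrics come exclusively from the
untouched outer test fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted

from .binary import run_bsrwpso
from .datasets import Dataset
from .fknn import FuzzyKNN
from .swarm import SwarmConfig

__all__ = [
    "MetricsReport",
    "SelectionReport",
    "SelectionConfig",
    "fitness_eval",
    "confusion_metrics",
    "stratified_kfold",
    "run_feature_selection",
    "repeated_selection_counts",
    "BinarySwarmFeatureSelector",
]

FITNESS_ALPHA = 0.99


@dataclass
class MetricsReport:
    """Binary-classification metrics from one confusion matrix."""

    accuracy: float
    sensitivity: float
    mcc: float
    f_measure: float
    confusion: tuple[int, int, int, int]  # (TP, FP, FN, TN)


@dataclass
class SelectionReport:
    """Per-feature selection counts and per-fold test metrics."""

    selection_counts: np.ndarray
    per_fold_metrics: list[MetricsReport]
    per_fold_masks: list[np.ndarray]
    repeats: int
    folds: int
    feature_names: list[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.per_fold_metrics]))


@dataclass
class SelectionConfig:
    """Settings of the wrapper pipeline.

    Swarm defaults follow the feature-selection setup: population 20,
    50 iterations, 10 outer folds.  The inner fitness error is a stratified
    hold-out of ``inner_holdout`` of the outer-training partition, fixed
    (seeded) per fold so each mask's fitness is deterministic.
    """

    population_size: int = 20
    iterations: int = 50
    folds: int = 10
    k: int = 5
    m: float = 2.0
    init_scheme: str = "crisp"
    inner_holdout: float = 0.2
    seed: int = 0
    positive_class: Optional[object] = None
    use_sobol: bool = True
    use_rrs: bool = True
    use_aws: bool = True


def fitness_eval(error_rate: float, R: int, D: int) -> float:
    """Wrapper fitness alpha*Error + (1-alpha)*R/D with alpha = 0.99.

    R = 0 returns the sentinel 1.0 so empty masks can never win.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error_rate must lie in [0, 1], got {error_rate}")
    if D < 1:
        raise ValueError("D must be >= 1")
    if not 0 <= R <= D:
        raise ValueError(f"R must lie in [0, {D}], got {R}")
    if R == 0:
        return 1.0
    return FITNESS_ALPHA * error_rate + (1.0 - FITNESS_ALPHA) * R / D


def confusion_metrics(TP: int, FP: int, FN: int, TN: int) -> MetricsReport:
    """Accuracy, sensitivity, MCC and F-measure from confusion counts.

    F-measure = TP / (TP + (FN + FP)/2); MCC is defined as 0 when its
    denominator vanishes.
    """
    counts = (TP, FP, FN, TN)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion matrix is empty")
    tp, fp, fn, tn = (float(c) for c in counts)
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    f_den = tp + (fn + fp) / 2.0
    f_measure = tp / f_den if f_den > 0 else 0.0
    return MetricsReport(
        accuracy=float(accuracy),
        sensitivity=float(sensitivity),
        mcc=float(mcc),
        f_measure=float(f_measure),
        confusion=(int(TP), int(FP), int(FN), int(TN)),
    )


def stratified_kfold(labels, folds: int, seed: int = 0):
    """Seeded stratified k-fold splits as (train_indices, test_indices)."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than folds={folds}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def _one_vs_rest_confusion(y_true, y_pred, positive) -> tuple[int, int, int, int]:
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    TP = int(np.sum(t & p))
    FP = int(np.sum(~t & p))
    FN = int(np.sum(t & ~p))
    TN = int(np.sum(~t & ~p))
    return TP, FP, FN, TN


def _mask_fitness_factory(X_in, y_in, X_hold, y_hold, config: SelectionConfig):
    """Fitness over masks with memoisation (masks recur as the swarm converges)."""
    D = X_in.shape[1]
    cache: dict[bytes, float] = {}

    def mask_fitness(mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=np.int8).tobytes()
        if key in cache:
            return cache[key]
        sel = np.flatnonzero(mask)
        if sel.size == 0:
            value = fitness_eval(0.0, 0, D)
        else:
            clf = FuzzyKNN(k=config.k, m=config.m, init_scheme=config.init_scheme)
            clf.fit(X_in[:, sel], y_in)
            error = float(np.mean(clf.predict(X_hold[:, sel]) != y_hold))
            value = fitness_eval(error, int(sel.size), D)
        cache[key] = value
        return value

    return mask_fitness


def run_feature_selection(
    dataset: Dataset, config: Optional[SelectionConfig] = None
) -> SelectionReport:
    """One repeat of outer-fold cross-validated wrapper selection.

    Per outer fold: fit a min-max scaler on the training partition, split
    it into an inner fit/hold-out pair, let bSRWPSO search masks against
    the hold-out FKNN error, then refit FKNN with the winning mask on the
    whole (scaled) outer-training partition and score it on the outer test
    fold.
    """
    if config is None:
        config = SelectionConfig()
    X, y = dataset.features, dataset.labels
    D = dataset.n_features
    positive = (
        config.positive_class
        if config.positive_class is not None
        else np.unique(y)[0]
    )
    splits = stratified_kfold(y, config.folds, seed=config.seed)
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * config.folds)

    masks: list[np.ndarray] = []
    metrics: list[MetricsReport] = []
    for fold, (train_idx, test_idx) in enumerate(splits):
        scaler = MinMaxScaler().fit(X[train_idx])
        X_tr = scaler.transform(X[train_idx])
        X_te = scaler.transform(X[test_idx])
        y_tr, y_te = y[train_idx], y[test_idx]

        X_in, X_hold, y_in, y_hold = train_test_split(
            X_tr,
            y_tr,
            test_size=config.inner_holdout,
            stratify=y_tr,
            random_state=int(seeds[2 * fold] % 2**31),
        )
        fitness = _mask_fitness_factory(X_in, y_in, X_hold, y_hold, config)
        swarm_cfg = SwarmConfig(
            dim=D,
            population_size=config.population_size,
            max_evaluations=10**9,
            lower_bound=0.0,
            upper_bound=1.0,
            seed=int(seeds[2 * fold + 1] % 2**31),
            use_sobol=config.use_sobol,
            use_rrs=config.use_rrs,
            use_aws=config.use_aws,
        )
        result = run_bsrwpso(fitness, D, swarm_cfg, iterations=config.iterations)
        mask = result.best_mask
        sel = np.flatnonzero(mask)

        clf = FuzzyKNN(k=config.k, m=config.m, init_scheme=config.init_scheme)
        clf.fit(X_tr[:, sel], y_tr)
        y_pred = clf.predict(X_te[:, sel])
        metrics.append(confusion_metrics(*_one_vs_rest_confusion(y_te, y_pred, positive)))
        masks.append(np.asarray(mask, dtype=int))

    counts = np.sum(np.vstack(masks), axis=0)
    return SelectionReport(
        selection_counts=counts,
        per_fold_metrics=metrics,
        per_fold_masks=masks,
        repeats=1,
        folds=config.folds,
        feature_names=list(dataset.feature_names),
    )


def repeated_selection_counts(
    dataset: Dataset, repeats: int, config: Optional[SelectionConfig] = None
) -> SelectionReport:
    """Aggregate ``repeats`` reseeded repeats of cross-validated selection.

    selection_counts[d] is the number of (repeat, fold) pairs whose winning
    mask included feature d, in [0, repeats * folds].
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if config is None:
        config = SelectionConfig()
    repeat_seeds = np.random.SeedSequence(config.seed).generate_state(repeats)

    all_masks: list[np.ndarray] = []
    all_metrics: list[MetricsReport] = []
    for r in range(repeats):
        rep_config = replace(config, seed=int(repeat_seeds[r] % 2**31))
        report = run_feature_selection(dataset, rep_config)
        all_masks.extend(report.per_fold_masks)
        all_metrics.extend(report.per_fold_metrics)

    counts = np.sum(np.vstack(all_masks), axis=0)
    return SelectionReport(
        selection_counts=counts,
        per_fold_metrics=all_metrics,
        per_fold_masks=all_masks,
        repeats=repeats,
        folds=config.folds,
        feature_names=list(dataset.feature_names),
    )


class BinarySwarmFeatureSelector(SelectorMixin, BaseEstimator):
    """scikit-learn-style selector: bSRWPSO search against FKNN hold-out error.

    ``fit`` scales the data, splits off a stratified hold-out, and runs the
    binary swarm once; the winning mask is exposed through ``get_support``
    and ``transform`` so the selector composes with sklearn pipelines.
    """

    def __init__(
        self,
        population_size: int = 20,
        iterations: int = 50,
        k: int = 5,
        m: float = 2.0,
        init_scheme: str = "crisp",
        inner_holdout: float = 0.2,
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.iterations = iterations
        self.k = k
        self.m = m
        self.init_scheme = init_scheme
        self.inner_holdout = inner_holdout
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.n_features_in_ = X.shape[1]
        cfg = SelectionConfig(
            population_size=self.population_size,
            iterations=self.iterations,
            k=self.k,
            m=self.m,
            init_scheme=self.init_scheme,
            inner_holdout=self.inner_holdout,
            seed=self.random_state,
        )
        scaler = MinMaxScaler().fit(X)
        Xs = scaler.transform(X)
        seeds = np.random.SeedSequence(self.random_state).generate_state(2)
        X_in, X_hold, y_in, y_hold = train_test_split(
            Xs,
            y,
            test_size=self.inner_holdout,
            stratify=y,
            random_state=int(seeds[0] % 2**31),
        )
        fitness = _mask_fitness_factory(X_in, y_in, X_hold, y_hold, cfg)
        swarm_cfg = SwarmConfig(
            dim=self.n_features_in_,
            population_size=self.population_size,
            max_evaluations=10**9,
            lower_bound=0.0,
            upper_bound=1.0,
            seed=int(seeds[1] % 2**31),
        )
        result = run_bsrwpso(
            fitness, self.n_features_in_, swarm_cfg, iterations=self.iterations
        )
        self.support_ = result.best_mask.astype(bool)
        self.best_fitness_ = result.best_fitness
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
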