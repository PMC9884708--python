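"""Tabular dataset container, CSV loading, and a synthetic clinical-style
classification generator.

The generator emulates the shape of a small dermatology cohort table: a few
hundred samples, ~36 non-negative continuous features on wildly different
scales (cell counts, percentages, IU/ml concentrations) with heavy right
skew, a binary class label, and a small planted subset of class-informative
features.  Informative features occupy the first ``n_informative`` columns
and carry a class-conditional mean shift of ``effect_size`` pooled standard
deviations, applied after the log-normal distortion so the standardized
mean difference in the generated data equals ``effect_size`` regardless of
skew.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "SyntheticSpec",
    "generate_synthetic_classification",
    "load_dataset_csv",
]


@dataclass
class Dataset:
    """Numeric feature matrix with class labels and feature names."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        n, d = self.features.shape
        if self.labels.shape[0] != n:
            raise ValueError("features and labels length mismatch")
        if not self.feature_names:
            self.feature_names = [f"f{j + 1:02d}" for j in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length mismatch")
        if np.unique(self.labels).size < 2:
            raise ValueError("dataset must contain at least 2 classes")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("dataset contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic clinical-style generator.

    effect_size is the class-mean shift in pooled-SD units of each
    informative feature; skew is the log-normal shape of the base features
    (0 disables the distortion); class_balance is the probability of the
    positive class (label 1).
    """

    n_samples: int = 300
    n_features: int = 36
    n_informative: int = 4
    effect_size: float = 2.0
    skew: float = 0.5
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie strictly in (0, 1)")
        if self.skew < 0:
            raise ValueError("skew must be non-negative")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")


def generate_synthetic_classification(spec: SyntheticSpec) -> Dataset:
    """Draw a synthetic cohort per ``spec``; fully seeded.

    Labels are 1 (positive/case, mean-shifted) and 2 (control).  Base
    features are iid standard normal, log-normally distorted when skew > 0;
    informative columns then receive the additive class shift; every column
    is made non-negative and rescaled by a fixed per-feature decade factor
    to mimic mixed clinical units.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    labels = np.where(rng.random(n) < spec.class_balance, 1, 2)
    z = rng.standard_normal((n, d))
    if spec.skew > 0:
        base = np.exp(spec.skew * z)
        s2 = spec.skew**2
        base_sd = float(np.sqrt((np.exp(s2) - 1.0) * np.exp(s2)))
    else:
        base = z
        base_sd = 1.0
    X = base
    shift = spec.effect_size * base_sd * (labels == 1).astype(float)
    X[:, : spec.n_informative] += shift[:, None]
    # non-negativity (log-normal base already is; the normal base is shifted)
    col_min = X.min(axis=0)
    X -= np.minimum(col_min, 0.0)
    scales = 10.0 ** rng.uniform(0.0, 2.0, d)
    X *= scales
    names = [
        f"inf{j + 1:02d}" if j < spec.n_informative else f"noise{j + 1:02d}"
        for j in range(d)
    ]
    return Dataset(features=X, labels=labels, feature_names=names)


def load_dataset_csv(path, label_column: str) -> Dataset:
    """Load a CSV (header row, numeric features, one label column).

    Labels are mapped to 1..C in first-appearance order.  Missing values
    and non-numeric feature cells are rejected with the offending
    row/column named.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(
            f"label column {label_column!r} not found; columns: {list(df.columns)}"
        )
    na = df.isna()
    if na.values.any():
        row = int(np.argmax(na.values.any(axis=1)))
        col = df.columns[int(np.argmax(na.values[row]))]
        raise ValueError(f"missing value at row {row}, column {col!r}")
    feature_cols = [c for c in df.columns if c != label_column]
    features = np.empty((len(df), len(feature_cols)))
    for j, c in enumerate(feature_cols):
        try:
            features[:, j] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in feature column {c!r}") from exc
    raw = df[label_column].to_numpy()
    seen: dict = {}
    labels = np.empty(len(raw), dtype=int)
    for i, v in enumerate(raw):
        if v not in seen:
            seen[v] = len(seen) + 1
        labels[i] = seen[v]
    return Dataset(features=features, labels=labels, feature_names=feature_cols)
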