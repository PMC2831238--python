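"""Expression-matrix I/O, stratified splitting and bootstrap subsetting.

The container is a plain samples × features matrix with −1/+1 class labels.
Splits and subsets are stratified so that per-class proportions stay within
one sample of the full-data proportions, and are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SplitPlan",
    "load_expression",
    "stratified_split",
    "bootstrap_subsets",
]


class ExpressionFormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """Two-class expression data: samples × features with ±1 labels.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``values``.
    feature_ids : list of str
        Unique feature (probe/gene) identifiers, one per column.
    values : ndarray of shape (n_samples, n_features)
        Real-valued expression, no missing entries.
    labels : ndarray of shape (n_samples,)
        Class labels encoded −1/+1.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExpressionFormatError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ExpressionFormatError("duplicate feature ids")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ExpressionFormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if np.isnan(self.values).any():
            raise ExpressionFormatError("values contain missing entries")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ExpressionFormatError("labels must be encoded -1/+1")
        if len(np.unique(self.labels)) != 2:
            raise ExpressionFormatError("exactly two classes required")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self._feature_lookup[feature_id]
        except AttributeError:
            self._feature_lookup = {f: i for i, f in enumerate(self.feature_ids)}
            return self._feature_lookup[feature_id]

    def column(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_index(feature_id)]

    def subset_samples(self, indices) -> "ExpressionMatrix":
        """Row-subset view copy keeping all features."""
        idx = np.asarray(list(indices), dtype=int)
        return ExpressionMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            values=self.values[idx],
            labels=self.labels[idx],
        )

    def save(self, matrix_path, labels_path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)
        df.to_csv(matrix_path, sep="\t", index_label="sample_id")
        lab = pd.DataFrame({"sample_id": self.sample_ids, "label": self.labels})
        lab.to_csv(labels_path, sep="\t", index=False)


@dataclass
class SplitPlan:
    """A stratified train/test partition of the sample index set."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    ratio: float

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        if set(self.train_indices) & set(self.test_indices):
            raise ValueError("train and test indices overlap")

    def save(self, path, sample_ids: list[str]) -> None:
        rows = [(sample_ids[i], "train") for i in self.train_indices]
        rows += [(sample_ids[i], "test") for i in self.test_indices]
        pd.DataFrame(rows, columns=["sample_id", "role"]).to_csv(path, sep="\t", index=False)

    @staticmethod
    def load(path, sample_ids: list[str], seed: int = -1, ratio: float = float("nan")) -> "SplitPlan":
        df = pd.read_csv(path, sep="\t")
        pos = {s: i for i, s in enumerate(sample_ids)}
        train = [pos[s] for s, r in zip(df["sample_id"], df["role"]) if r == "train"]
        test = [pos[s] for s, r in zip(df["sample_id"], df["role"]) if r == "test"]
        return SplitPlan(np.array(train), np.array(test), seed=seed, ratio=ratio)


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def load_expression(matrix_path, labels_path, missing_policy: str = "drop_feature") -> ExpressionMatrix:
    """Load an expression matrix and its sample labels from tabular text.

    The matrix file has a header row of feature ids and a first column of
    sample ids; the labels file maps sample id → class label (two columns).
    Samples without a label are dropped. Labels are encoded −1/+1 by sorted
    order of the two distinct raw values.

    Parameters
    ----------
    missing_policy : {"drop_feature", "mean_impute"}
        What to do with missing cells: drop the whole feature, or impute the
        feature mean (features that are entirely missing are dropped either
        way).
    """
    if missing_policy not in ("drop_feature", "mean_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    raw = _read_table(matrix_path)
    if raw.columns.duplicated().any():
        dupes = raw.columns[raw.columns.duplicated()].tolist()
        raise ExpressionFormatError(f"duplicate feature ids: {dupes}")
    if raw.index.duplicated().any():
        raise ExpressionFormatError("duplicate sample ids")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ExpressionFormatError(
            f"non-numeric cell at sample {raw.index[r]!r}, feature {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )

    sep = "," if str(labels_path).endswith(".csv") else "\t"
    lab = pd.read_csv(labels_path, sep=sep)
    lab = lab.dropna()
    label_map = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1]))

    keep = [s for s in numeric.index.astype(str) if s in label_map]
    numeric = numeric.loc[keep]
    raw_labels = [label_map[s] for s in keep]
    classes = sorted(set(raw_labels), key=str)
    if len(classes) != 2:
        raise ExpressionFormatError(f"expected exactly 2 classes, got {classes}")
    labels = np.array([-1 if l == classes[0] else 1 for l in raw_labels])
    for cls in (-1, 1):
        if (labels == cls).sum() < 2:
            raise ExpressionFormatError("fewer than 2 samples in one class")

    if missing_policy == "drop_feature":
        numeric = numeric.dropna(axis=1, how="any")
    else:
        numeric = numeric.dropna(axis=1, how="all")
        numeric = numeric.fillna(numeric.mean())

    return ExpressionMatrix(
        sample_ids=[str(s) for s in numeric.index],
        feature_ids=[str(f) for f in numeric.columns],
        values=numeric.values,
        labels=labels,
    )


def _per_class_indices(labels: np.ndarray) -> dict[int, np.ndarray]:
    return {c: np.flatnonzero(labels == c) for c in (-1, 1)}


def stratified_split(data: ExpressionMatrix, ratio: float, seed: int) -> SplitPlan:
    """Partition samples into train/test keeping class proportions.

    Each class contributes round(ratio · n_class) samples to the train set,
    so a 4:1 split of balanced data is exactly balanced on both sides.
    Deterministic under ``seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0,1), got {ratio}")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls, idx in _per_class_indices(data.labels).items():
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        perm = rng.permutation(idx)
        n_train = int(round(ratio * len(idx)))
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return SplitPlan(np.sort(train), np.sort(test), seed=seed, ratio=ratio)


def bootstrap_subsets(
    data: ExpressionMatrix,
    K: int,
    fraction: float,
    seed: int,
    with_replacement: bool = False,
) -> list[np.ndarray]:
    """Draw K stratified sample-index subsets of size round(fraction·n).

    Default is sampling WITHOUT replacement (each subset holds a distinct
    ``fraction`` share of the data per class); ``with_replacement`` switches
    to classical bootstrap resampling at the same per-class sizes.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0,1], got {fraction}")
    rng = np.random.default_rng(seed)
    per_class = _per_class_indices(data.labels)
    for cls, idx in per_class.items():
        if int(round(fraction * len(idx))) < 1:
            raise ValueError(f"subset would lose class {cls} entirely")
    subsets = []
    for _ in range(K):
        chosen = []
        for idx in per_class.values():
            n_take = int(round(fraction * len(idx)))
            if with_replacement:
                chosen.extend(rng.choice(idx, size=n_take, replace=True))
            else:
                chosen.extend(rng.permutation(idx)[:n_take])
        subsets.append(np.sort(chosen))
    return subsets
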