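"""Dataset container, CSV loading, standardization, and splitting."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = ["Dataset", "read_csv", "standardize", "inverse_standardize",
           "stratified_split", "kfold"]


@dataclass
class Dataset:
    """An ``n x d`` pattern matrix with class labels.

    Attributes
    ----------
    X:
        Real-valued pattern matrix, one row per pattern.
    y:
        Length-``n`` class labels (any hashable values).
    attribute_names:
        Length-``d`` column names.
    class_labels:
        Distinct labels in declaration order; prediction tie-breaks use
        this order.
    standardized:
        Whether ``X`` has been transformed to per-attribute mean 0 and
        variance 1.
    standardization_params:
        Per-attribute ``(mean, sd)`` used for the transform, if any.
    """

    X: np.ndarray
    y: np.ndarray
    attribute_names: list[str]
    class_labels: list
    standardized: bool = False
    standardization_params: Optional[list[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, d = self.X.shape
        if d < 1:
            raise ValueError("need at least one attribute")
        if n < 2:
            raise ValueError("need at least two patterns")
        if len(self.y) != n:
            raise ValueError("X and y length mismatch")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if len(self.attribute_names) != d:
            raise ValueError("attribute_names length must equal d")
        known = set(self.class_labels)
        unknown = {label for label in self.y if label not in known}
        if unknown:
            raise ValueError(f"labels {unknown!r} not in class_labels")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def class_mask(self, cls) -> np.ndarray:
        return np.asarray([label == cls for label in self.y])

    def class_size(self, cls) -> int:
        return int(self.class_mask(cls).sum())

    def domain(self) -> list[tuple[float, float]]:
        """Per-attribute ``[min, max]`` bounding box over the patterns."""
        return [(float(lo), float(hi))
                for lo, hi in zip(self.X.min(axis=0), self.X.max(axis=0))]

    def subset(self, index: np.ndarray) -> "Dataset":
        """Row subset preserving declared class order and metadata."""
        return replace(self, X=self.X[index], y=self.y[index])


def read_csv(path, class_column: Union[str, int, None] = None) -> Dataset:
    """Load a headered CSV of numeric attributes plus one class column.

    Parameters
    ----------
    class_column:
        Column name or positional index of the class labels; defaults
        to the last column.

    Raises
    ------
    ValueError
        On an empty file, missing values (with a count and first cell
        named), or non-numeric attribute cells (with row/column named).
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty file: {path}") from None
    if frame.shape[0] == 0 or frame.shape[1] < 2:
        raise ValueError(f"{path}: need at least one data row and two columns")

    if class_column is None:
        class_column = frame.columns[-1]
    elif isinstance(class_column, int):
        class_column = frame.columns[class_column]
    elif class_column not in frame.columns:
        raise ValueError(f"class column {class_column!r} not in header")

    y_raw = frame[class_column]
    attrs = frame.drop(columns=[class_column])

    if y_raw.isna().any() or attrs.isna().any().any():
        n_missing = int(attrs.isna().sum().sum() + y_raw.isna().sum())
        where = [(int(i), str(c)) for c in attrs.columns
                 for i in attrs.index[attrs[c].isna()]]
        where += [(int(i), str(class_column)) for i in y_raw.index[y_raw.isna()]]
        first = min(where)
        raise ValueError(
            f"{n_missing} missing value(s); first at row {first[0]}, "
            f"column {first[1]!r}"
        )

    X = np.empty(attrs.shape, dtype=float)
    for j, col in enumerate(attrs.columns):
        converted = pd.to_numeric(attrs[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = int(attrs.index[bad][0])
            raise ValueError(
                f"non-numeric value {attrs[col].iloc[row]!r} at row {row}, "
                f"column {col!r}"
            )
        X[:, j] = converted.to_numpy()

    y = y_raw.to_numpy(dtype=object)
    class_labels = list(dict.fromkeys(y))
    return Dataset(X=X, y=y, attribute_names=[str(c) for c in attrs.columns],
                   class_labels=class_labels)


def standardize(
    data: Dataset,
    params: Optional[list[tuple[float, float]]] = None,
) -> Dataset:
    """Transform each attribute to mean 0, variance 1 (population variance).

    With ``params`` given, applies a previously fitted transform (use the
    training set's parameters on test data to avoid leakage).  Constant
    attributes map to all-zeros with sd recorded as 1.
    """
    if data.standardized:
        raise ValueError("dataset is already standardized")
    if params is None:
        means = data.X.mean(axis=0)
        sds = data.X.std(axis=0)  # population (1/n) variance
        sds = np.where(sds == 0.0, 1.0, sds)
        params = [(float(m), float(s)) for m, s in zip(means, sds)]
    means = np.array([m for m, _ in params])
    sds = np.array([s for _, s in params])
    Xs = (data.X - means) / sds
    return replace(data, X=Xs, standardized=True, standardization_params=params)


def inverse_standardize(data: Dataset) -> Dataset:
    """Undo :func:`standardize`, recovering the raw attribute values."""
    if not data.standardized or data.standardization_params is None:
        raise ValueError("dataset is not standardized")
    means = np.array([m for m, _ in data.standardization_params])
    sds = np.array([s for _, s in data.standardization_params])
    return replace(data, X=data.X * sds + means, standardized=False,
                   standardization_params=None)


def stratified_split(
    data: Dataset, test_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Per-class proportional train/test split, deterministic under ``seed``."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    sizes = {cls: data.class_size(cls) for cls in data.class_labels}
    for cls, size in sizes.items():
        if size < 2:
            raise ValueError(f"class {cls!r} has {size} pattern(s); need >= 2")
        if int(round(size * test_fraction)) < 1 or int(round(size * test_fraction)) >= size:
            raise ValueError(
                f"test_fraction {test_fraction} leaves class {cls!r} empty "
                "in one partition"
            )
    idx = np.arange(data.n)
    strat = np.asarray([str(v) for v in data.y])
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=strat)
    return data.subset(np.sort(train_idx)), data.subset(np.sort(test_idx))


def kfold(data: Dataset, k: int, seed: int) -> list[tuple[Dataset, Dataset]]:
    """Stratified k-fold partition; test folds are disjoint and cover the data."""
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls in data.class_labels:
        if data.class_size(cls) < k:
            raise ValueError(
                f"class {cls!r} has fewer than k={k} patterns")
    strat = np.asarray([str(v) for v in data.y])
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in splitter.split(data.X, strat):
        folds.append((data.subset(train_idx), data.subset(test_idx)))
    return folds
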