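"""Labelled expression-matrix I/O, normalization and stratified folding.

The in-memory substrate for every evaluator in this package is
:class:`ExpressionDataset`: a dense samples x genes matrix with one
categorical class label per sample and one identifier per gene column.
Files are delimited text, samples as rows by default (``transpose=True``
handles the common genes-as-rows microarray dump).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


class DatasetFormatError(ValueError):
    """A file or matrix violates the expression-dataset contract."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A labelled samples x genes expression matrix.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Expression levels; finite floats, no missing entries.
    labels : ndarray of shape (n_samples,)
        One class label per sample; at least two classes, each with at
        least two samples (anything smaller cannot be stratified).
    gene_ids : tuple of str
        One unique identifier per gene column, file order preserved.
    name : str
        Free-text dataset tag used in reports.
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if values.ndim != 2:
            raise DatasetFormatError("expression values must be a 2-D matrix")
        if values.shape[0] != labels.shape[0]:
            raise DatasetFormatError(
                f"{values.shape[0]} sample rows but {labels.shape[0]} labels"
            )
        if values.shape[1] != len(self.gene_ids):
            raise DatasetFormatError(
                f"{values.shape[1]} gene columns but {len(self.gene_ids)} gene ids"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DatasetFormatError(
                f"non-finite expression value at sample {bad[0]}, gene {bad[1]}"
            )
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise DatasetFormatError(f"duplicate gene identifier {g!r}")
            seen.add(g)
        classes = np.unique(labels)
        if classes.size < 2:
            raise DatasetFormatError("need at least 2 classes")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def smallest_class_size(self) -> int:
        return int(np.unique(self.labels, return_counts=True)[1].min())

    def check_foldable(self) -> None:
        """Raise unless every class has >= 2 samples (stratification needs it)."""
        classes, counts = np.unique(self.labels, return_counts=True)
        if counts.min() < 2:
            small = classes[counts.argmin()]
            raise DatasetFormatError(
                f"class {small!r} has {counts.min()} sample(s); stratified "
                "folding needs >= 2 per class"
            )

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        return replace(self, values=values)


@dataclass(frozen=True)
class FoldAssignment:
    """A stratified k-fold partition of the sample index set.

    ``fold_index[i]`` is the fold (in ``[0, k)``) holding sample ``i`` as
    a test sample; every fold is non-empty and class proportions per fold
    match the global proportions within one sample.
    """

    fold_index: np.ndarray
    k: int

    def __post_init__(self) -> None:
        fold_index = np.asarray(self.fold_index, dtype=int)
        object.__setattr__(self, "fold_index", fold_index)
        present = np.unique(fold_index)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError("every fold in [0, k) must be non-empty")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def load_expression_delimited(
    path: str | Path,
    label_column: str | int = "label",
    delimiter: str = ",",
    *,
    transpose: bool = False,
    impute_mean: bool = False,
    name: str | None = None,
) -> ExpressionDataset:
    """Read a labelled expression matrix from delimited text.

    The file has a header row of gene identifiers plus one label column
    (``label_column`` names it, or gives its positional index). With
    ``transpose=True`` the file is genes-as-rows and is transposed after
    reading; the label column then refers to the transposed frame.

    Missing values are rejected unless ``impute_mean=True``, in which
    case each gene's missing entries are replaced by that gene's mean.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # pandas silently renames duplicate header names, so check the raw header
    import csv as _csv

    with open(path, newline="") as fh:
        header = next(_csv.reader(fh, delimiter=delimiter), [])
    dupes = {h for h in header if header.count(h) > 1}
    if dupes and not transpose:
        raise DatasetFormatError(f"duplicate gene identifier {sorted(dupes)[0]!r}")
    frame = pd.read_csv(path, sep=delimiter, header=0)
    if transpose:
        frame = frame.set_index(frame.columns[0]).T.reset_index(drop=True)
        frame.columns = [str(c) for c in frame.columns]
    if isinstance(label_column, int):
        try:
            label_name = frame.columns[label_column]
        except IndexError:
            raise DatasetFormatError(
                f"label column index {label_column} out of range"
            ) from None
    else:
        label_name = label_column
        if label_name not in frame.columns:
            raise DatasetFormatError(
                f"label column {label_name!r} not found; columns are "
                f"{list(frame.columns)[:8]}..."
            )
    labels = frame[label_name].astype(str).to_numpy()
    expr = frame.drop(columns=[label_name])
    numeric = expr.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~expr.isna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise DatasetFormatError(
            f"non-numeric cell {expr.iat[row, col]!r} at row {row}, "
            f"column {expr.columns[col]!r}"
        )
    if numeric.isna().to_numpy().any():
        if not impute_mean:
            row, col = np.argwhere(numeric.isna().to_numpy())[0]
            raise DatasetFormatError(
                f"missing value at row {row}, column {numeric.columns[col]!r} "
                "(pass impute_mean=True to impute per-gene means)"
            )
        numeric = numeric.fillna(numeric.mean())
    return ExpressionDataset(
        values=numeric.to_numpy(dtype=float),
        labels=labels,
        gene_ids=tuple(str(c) for c in numeric.columns),
        name=name if name is not None else path.stem,
    )


def load_expression_arff(
    path: str | Path, label_column: str = "label", *, name: str | None = None
) -> ExpressionDataset:
    """Read an ARFF file (@attribute/@data) into an :class:`ExpressionDataset`."""
    from scipy.io import arff

    path = Path(path)
    data, meta = arff.loadarff(str(path))
    frame = pd.DataFrame(data)
    for col in frame.columns:
        if frame[col].dtype == object:
            frame[col] = frame[col].str.decode("utf-8")
    if label_column not in frame.columns:
        raise DatasetFormatError(f"label attribute {label_column!r} not in ARFF")
    labels = frame[label_column].astype(str).to_numpy()
    expr = frame.drop(columns=[label_column])
    return ExpressionDataset(
        values=expr.to_numpy(dtype=float),
        labels=labels,
        gene_ids=tuple(str(c) for c in expr.columns),
        name=name if name is not None else path.stem,
    )


def write_expression_csv(
    dataset: ExpressionDataset, path: str | Path, label_column: str = "label"
) -> None:
    """Write the dataset back to CSV (genes as columns plus the label column)."""
    frame = pd.DataFrame(dataset.values, columns=list(dataset.gene_ids))
    frame[label_column] = dataset.labels
    frame.to_csv(path, index=False)


def minmax_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Rescale every gene column to [0, 1] via (x - min) / (max - min).

    Constant columns carry no information and map to all zeros. The map
    is idempotent on already-normalized data.
    """
    values = dataset.values
    col_min = values.min(axis=0)
    col_range = values.max(axis=0) - col_min
    safe = np.where(col_range > 0, col_range, 1.0)
    out = (values - col_min) / safe
    out[:, col_range == 0] = 0.0
    return dataset.with_values(out)


def is_normalized(dataset: ExpressionDataset, tol: float = 1e-12) -> bool:
    v = dataset.values
    return bool(v.min() >= -tol and v.max() <= 1 + tol)


def make_stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> FoldAssignment:
    """Assign each sample to one of ``k`` stratified folds, deterministically.

    ``k`` is capped at the smallest class count (with a warning) so every
    fold can hold at least one sample of every class.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("stratified folding requires at least 2 classes")
    if k < 2:
        raise ValueError("k must be >= 2")
    smallest = int(counts.min())
    if k > smallest:
        warnings.warn(
            f"k={k} exceeds the smallest class count {smallest}; using k={smallest}",
            stacklevel=2,
        )
        k = smallest
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(labels.shape[0], dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros_like(labels), labels)):
        fold_index[test_idx] = fold
    return FoldAssignment(fold_index=fold_index, k=k)
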