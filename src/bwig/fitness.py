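"""The wrapper objective: KNN cross-validated error weighted against subset size.

A candidate solution is a continuous genotype in [LB, UB]^N decoded to a
binary gene mask (entry selected iff its value exceeds a threshold). The
mask is scored as

    fitness = alpha * error + (1 - alpha) * n_selected / N

where ``error`` is the stratified k-fold cross-validated error rate of a
K-nearest-neighbour classifier restricted to the selected gene columns.
Lower is better. alpha close to 1 makes accuracy dominate, with the size
term breaking ties toward smaller subsets. An empty mask scores the worst
possible fitness (1.0) rather than raising, so optimizers can traverse it.

Determinism contract: folds are drawn once per evaluator (from
``cv_seed``) and reused for every call, distance ties go to the lower
sample index, and residual vote ties go to the nearest neighbour's label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import ExpressionDataset, FoldAssignment, make_stratified_folds


@dataclass(frozen=True)
class FitnessSpec:
    """Configuration of the wrapper fitness evaluator.

    alpha weights the classification error; beta = 1 - alpha weights the
    selected-gene fraction. knn_k must be odd (two-class vote ties cannot
    then arise from a full neighbourhood). cv_folds is capped at the
    smallest class size when folds are built.
    """

    alpha: float = 0.99
    knn_k: int = 5
    cv_folds: int = 10
    cv_seed: int = 0
    empty_mask_penalty: float = 1.0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be a positive odd integer")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


@dataclass(frozen=True)
class EvaluatedSolution:
    """A scored gene mask: error rate, subset size and combined fitness."""

    mask: np.ndarray
    error_rate: float
    n_selected: int
    fitness: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)


def decode_mask(genotype: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a continuous genotype: gene i selected iff genotype[i] > threshold."""
    return np.asarray(genotype, dtype=float) > threshold


def build_cv_folds(dataset: ExpressionDataset, spec: FitnessSpec) -> FoldAssignment:
    """The fold plan a spec implies for a dataset.

    ``cv_folds >= n_samples`` requests leave-one-out (each sample its own
    fold); otherwise stratified k-fold with k capped at the smallest
    class size.
    """
    dataset.check_foldable()
    if spec.cv_folds >= dataset.n_samples:
        return FoldAssignment(
            fold_index=np.arange(dataset.n_samples), k=dataset.n_samples
        )
    k = min(spec.cv_folds, dataset.smallest_class_size())
    return make_stratified_folds(dataset.labels, k, spec.cv_seed)


def _knn_predict(
    dist: np.ndarray, train_codes: np.ndarray, k: int, n_classes: int
) -> np.ndarray:
    """Majority vote over the k nearest training samples, fully deterministic.

    ``dist`` is (n_test, n_train); train columns are in ascending original
    sample index order, so the stable argsort resolves exact distance ties
    toward the lower sample index. A residual vote tie is broken by the
    label of the nearest neighbour belonging to a tied class.
    """
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    neighbour_codes = train_codes[order]
    predictions = np.empty(dist.shape[0], dtype=int)
    for i in range(dist.shape[0]):
        counts = np.bincount(neighbour_codes[i], minlength=n_classes)
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if winners.size == 1:
            predictions[i] = winners[0]
        else:
            in_tie = np.isin(neighbour_codes[i], winners)
            predictions[i] = neighbour_codes[i][np.argmax(in_tie)]
    return predictions


def knn_cv_error(
    dataset: ExpressionDataset,
    mask: np.ndarray,
    spec: FitnessSpec,
    folds: FoldAssignment | None = None,
) -> float:
    """Stratified k-fold CV error of a KNN classifier on the masked genes.

    Returns the misclassified fraction over all samples. If a training
    fold holds fewer samples than ``knn_k``, k is reduced for that fold
    (with a warning). Deterministic for a fixed ``cv_seed``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no genes; route empty masks through evaluate()")
    if folds is None:
        folds = build_cv_folds(dataset, spec)
    classes, codes = np.unique(dataset.labels, return_inverse=True)
    X = dataset.values[:, mask]
    errors = 0
    for fold in range(folds.k):
        test_idx = folds.test_indices(fold)
        train_idx = folds.train_indices(fold)
        k = spec.knn_k
        if train_idx.size < k:
            warnings.warn(
                f"training fold has {train_idx.size} samples < knn_k={k}; reducing k",
                stacklevel=2,
            )
            k = train_idx.size
        dist = cdist(X[test_idx], X[train_idx], metric="sqeuclidean")
        pred = _knn_predict(dist, codes[train_idx], k, classes.size)
        errors += int(np.sum(pred != codes[test_idx]))
    return errors / dataset.n_samples


class WrapperFitnessEvaluator:
    """Scores genotypes against one dataset with fixed folds and a mask cache.

    Folds are drawn once at construction from ``spec.cv_seed`` and reused
    for every call, so the objective is deterministic within a run and
    best-so-far traces are meaningful. Results are cached per distinct
    mask; ``n_calls`` counts every evaluation request (the optimizer's
    budget), ``n_cv_computations`` only the cache misses.
    """

    def __init__(self, dataset: ExpressionDataset, spec: FitnessSpec):
        self.dataset = dataset
        self.spec = spec
        self.folds = build_cv_folds(dataset, spec)
        self._cache: dict[bytes, EvaluatedSolution] = {}
        self.n_calls = 0
        self.n_cv_computations = 0

    def evaluate_mask(self, mask: np.ndarray) -> EvaluatedSolution:
        mask = np.asarray(mask, dtype=bool)
        self.n_calls += 1
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        n_selected = int(mask.sum())
        if n_selected == 0:
            result = EvaluatedSolution(
                mask=mask,
                error_rate=1.0,
                n_selected=0,
                fitness=self.spec.empty_mask_penalty,
            )
        else:
            self.n_cv_computations += 1
            error = knn_cv_error(self.dataset, mask, self.spec, folds=self.folds)
            fitness = (
                self.spec.alpha * error
                + self.spec.beta * n_selected / self.dataset.n_genes
            )
            result = EvaluatedSolution(
                mask=mask, error_rate=error, n_selected=n_selected, fitness=fitness
            )
        self._cache[key] = result
        return result

    def evaluate_genotype(self, genotype: np.ndarray) -> EvaluatedSolution:
        return self.evaluate_mask(decode_mask(genotype, self.spec.threshold))


def evaluate(
    dataset: ExpressionDataset, genotype: np.ndarray, spec: FitnessSpec
) -> EvaluatedSolution:
    """One-shot genotype evaluation (builds a throwaway evaluator)."""
    return WrapperFitnessEvaluator(dataset, spec).evaluate_genotype(genotype)


def exhaustive_best_mask(
    evaluator: WrapperFitnessEvaluator, n_genes: int | None = None
) -> EvaluatedSolution:
    """Brute-force optimum over all 2**n non-empty masks (oracle for tests).

    Feasible only for small gene counts; refuses n > 16.
    """
    n = n_genes if n_genes is not None else evaluator.dataset.n_genes
    if n > 16:
        raise ValueError("exhaustive search is limited to <= 16 genes")
    best: EvaluatedSolution | None = None
    for bits in range(1, 2**n):
        mask = np.array([(bits >> j) & 1 for j in range(n)], dtype=bool)
        sol = evaluator.evaluate_mask(mask)
        if (
            best is None
            or sol.fitness < best.fitness
            or (sol.fitness == best.fitness and sol.n_selected < best.n_selected)
        ):
            best = sol
    assert best is not None
    return best
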