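"""Synthetic expression matrices with planted class-informative genes.

Emulates the shape of public microarray benchmarks — tens of samples,
hundreds to thousands of genes, 2-4 classes — with a small planted set of
informative genes whose class-conditional means are separated by a
controlled effect size, buried among class-independent noise genes. The
planted truth is returned alongside the data (never written into the
matrix) so selection-recovery metrics are computable by tests.

The model is Gaussian class-conditional: realism targets planted-truth
recovery, not microarray marginals. No correlated gene blocks, dropout or
zero inflation are simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import ExpressionDataset, minmax_normalize


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generator.

    ``effect_size`` is the separation between adjacent class means of an
    informative gene, in units of ``noise_sd``; 0 makes labels independent
    of the data. ``class_proportions`` defaults to balanced classes.
    """

    n_samples: int
    n_genes: int
    n_informative: int
    n_classes: int = 2
    effect_size: float = 3.0
    noise_sd: float = 1.0
    class_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("need 0 <= n_informative <= n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        props = self.class_proportions
        if props is None:
            props = tuple([1.0 / self.n_classes] * self.n_classes)
            object.__setattr__(self, "class_proportions", props)
        props = tuple(float(p) for p in props)
        object.__setattr__(self, "class_proportions", props)
        if len(props) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if abs(sum(props) - 1.0) > 1e-9 or min(props) <= 0:
            raise ValueError("class_proportions must be positive and sum to 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: which genes are informative and their class means."""

    informative_indices: frozenset[int]
    class_means: np.ndarray  # (n_classes, n_informative), column order = sorted indices

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "informative_indices", frozenset(int(i) for i in self.informative_indices)
        )
        object.__setattr__(self, "class_means", np.asarray(self.class_means, dtype=float))


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    """Deterministic per-class sample counts: largest-remainder apportionment."""
    target = np.array(spec.class_proportions) * spec.n_samples
    counts = np.floor(target).astype(int)
    remainder = spec.n_samples - counts.sum()
    order = np.argsort(-(target - counts), kind="stable")
    counts[order[:remainder]] += 1
    if counts.min() < 2:
        raise ValueError(
            "class proportions leave a class with fewer than 2 samples; "
            "increase n_samples or rebalance"
        )
    return counts


def generate_synthetic(spec: SyntheticSpec) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw a labelled expression matrix with planted informative genes.

    Informative gene j in class c is Normal(mu_cj, noise_sd) with class
    means spaced ``effect_size * noise_sd`` apart and centred on the
    background level; every other gene is iid Normal(background, noise_sd)
    independent of the class. The returned matrix is min-max normalized.
    Bit-identical output for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)
    labels = np.repeat([f"C{c}" for c in range(spec.n_classes)], counts)
    rng.shuffle(labels)
    class_code = np.array([int(lab[1:]) for lab in labels])

    background = 0.5  # nominal centre of the (later rescaled) expression range
    values = rng.normal(background, spec.noise_sd, size=(spec.n_samples, spec.n_genes))

    informative = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    )
    offsets = (
        np.arange(spec.n_classes) - (spec.n_classes - 1) / 2.0
    ) * spec.effect_size * spec.noise_sd
    class_means = background + np.tile(offsets[:, None], (1, spec.n_informative))
    for col, gene in enumerate(informative):
        mu = class_means[class_code, col]
        values[:, gene] = rng.normal(mu, spec.noise_sd)

    dataset = minmax_normalize(
        ExpressionDataset(
            values=values,
            labels=labels,
            gene_ids=tuple(f"g{j}" for j in range(spec.n_genes)),
            name=f"synthetic-{spec.seed}",
        )
    )
    truth = SyntheticTruth(
        informative_indices=frozenset(int(i) for i in informative),
        class_means=class_means,
    )
    return dataset, truth


def generate_tiny_separable(
    n_samples: int, n_genes: int, informative_index: int, seed: int = 0
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """A two-class fixture where exactly one gene perfectly separates the classes.

    The informative gene sits below 0.5 for class 0 and above 0.5 for
    class 1 with a wide margin; every other gene is uniform noise. The
    gene count is capped at 12 so exhaustive enumeration of all 2**n_genes
    masks stays feasible, making this the oracle fixture for optimizer tests.
    """
    if n_genes > 12:
        raise ValueError("n_genes must be <= 12 (exhaustive mask enumeration)")
    if not 0 <= informative_index < n_genes:
        raise ValueError(f"informative_index {informative_index} out of range")
    if n_samples < 4:
        raise ValueError("need at least 4 samples (2 per class)")
    rng = np.random.default_rng(seed)
    n0 = n_samples // 2
    labels = np.array(["C0"] * n0 + ["C1"] * (n_samples - n0))
    values = rng.uniform(0.0, 1.0, size=(n_samples, n_genes))
    values[:n0, informative_index] = rng.uniform(0.0, 0.2, size=n0)
    values[n0:, informative_index] = rng.uniform(0.8, 1.0, size=n_samples - n0)
    dataset = minmax_normalize(
        ExpressionDataset(
            values=values,
            labels=labels,
            gene_ids=tuple(f"g{j}" for j in range(n_genes)),
            name=f"tiny-separable-{seed}",
        )
    )
    truth = SyntheticTruth(
        informative_indices=frozenset({informative_index}),
        class_means=np.array([[0.1], [0.9]]),
    )
    return dataset, truth


def write_synthetic(
    dataset: ExpressionDataset, truth: SyntheticTruth, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the dataset CSV plus a truth JSON; returns the two paths."""
    from .datasets import write_expression_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_path = out_dir / f"{dataset.name or 'synthetic'}.csv"
    truth_path = out_dir / f"{dataset.name or 'synthetic'}.truth.json"
    write_expression_csv(dataset, data_path)
    truth_path.write_text(
        json.dumps(
            {
                "informative": sorted(truth.informative_indices),
                "class_means": truth.class_means.tolist(),
            },
            indent=2,
        )
        + "\n"
    )
    return data_path, truth_path
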