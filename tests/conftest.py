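import numpy as np
import pytest

from bwig import (
    FitnessSpec,
    WrapperFitnessEvaluator,
    SyntheticSpec,
    generate_synthetic,
    generate_tiny_separable,
)


@pytest.fixture(scope="session")
def tiny_sep():
    """20 samples x 8 genes; gene 3 perfectly separates the two classes."""
    return generate_tiny_separable(20, 8, informative_index=3, seed=7)


@pytest.fixture(scope="session")
def loocv_spec():
    """Leave-one-out 5-NN evaluator spec (cv_folds >= n_samples requests LOOCV)."""
    return FitnessSpec(alpha=0.99, knn_k=5, cv_folds=20, cv_seed=0)


@pytest.fixture(scope="session")
def tiny_evaluator(tiny_sep, loocv_spec):
    dataset, _ = tiny_sep
    return WrapperFitnessEvaluator(dataset, loocv_spec)


@pytest.fixture(scope="session")
def small_synth():
    """A quick 30 x 40 two-class instance for structural optimizer tests."""
    spec = SyntheticSpec(
        n_samples=30, n_genes=40, n_informative=3, effect_size=2.0, seed=5
    )
    return generate_synthetic(spec)
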