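"""Scikit-learn-style gene selectors wrapping the BWO, IG and BWO-IG runners.

These estimators follow the sklearn feature-selector contract
(``SelectorMixin``): ``fit(X, y)`` runs the wrapper search, ``support_``
holds the selected-gene mask, and ``transform(X)`` restricts a matrix to
the selected columns, so the selectors compose with pipelines and model
selection. Module-level runner functions (``run_bwo``, ``run_ig``,
``run_bwo_ig``) remain available for users who work with
:class:`~bwig.datasets.ExpressionDataset` directly.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_random_state

from .bwo import BWOConfig
from .datasets import ExpressionDataset, minmax_normalize
from .fitness import FitnessSpec
from .hybrid import VALID_METHODS, HybridConfig, run_method
from .ig import IGConfig


class BaseWrapperGeneSelector(SelectorMixin, BaseEstimator):
    """Shared machinery of the wrapper selectors; subclasses fix ``method``.

    Parameters mirror the optimizer and fitness configurations: ``alpha``
    weighs CV error against selected-gene fraction (beta = 1 - alpha),
    ``knn_k``/``cv_folds`` configure the KNN wrapper evaluator, the rest
    parameterize the search. ``normalize=True`` (default) min-max rescales
    every gene column to [0, 1] before evaluation. ``random_state`` is the
    master seed; None draws one from global NumPy state.

    Fitted attributes: ``support_`` (boolean mask over input columns),
    ``best_fitness_``, ``cv_error_``, ``n_selected_`` and the full
    ``trace_`` (a :class:`~bwig.bwo.RunTrace`).
    """

    method: str = "bwo-ig"

    def __init__(
        self,
        *,
        alpha: float = 0.99,
        knn_k: int = 5,
        cv_folds: int = 10,
        pop_size: int = 10,
        max_iterations: int = 100,
        pr: float = 0.6,
        mr: float = 0.4,
        ig_period: int = 10,
        ig_iterations: int = 10,
        destruct_frac: float = 0.2,
        t_scale: float = 1.0,
        normalize: bool = True,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.knn_k = knn_k
        self.cv_folds = cv_folds
        self.pop_size = pop_size
        self.max_iterations = max_iterations
        self.pr = pr
        self.mr = mr
        self.ig_period = ig_period
        self.ig_iterations = ig_iterations
        self.destruct_frac = destruct_frac
        self.t_scale = t_scale
        self.normalize = normalize
        self.random_state = random_state

    def _seed(self) -> int:
        if isinstance(self.random_state, numbers.Integral):
            return int(self.random_state)
        rng = check_random_state(self.random_state)
        return int(rng.randint(2**31))

    def _build_config(self, seed: int) -> HybridConfig:
        return HybridConfig(
            bwo=BWOConfig(
                pop_size=self.pop_size,
                max_iterations=self.max_iterations,
                pr=self.pr,
                mr=self.mr,
                seed=seed,
            ),
            ig=IGConfig(
                destruct_frac=self.destruct_frac,
                ig_iterations=self.ig_iterations,
                t_scale=self.t_scale,
                seed=seed,
            ),
            fitness=FitnessSpec(
                alpha=self.alpha,
                knn_k=self.knn_k,
                cv_folds=self.cv_folds,
                cv_seed=seed,
            ),
            ig_period=min(self.ig_period, max(1, self.max_iterations)),
            seed=seed,
        )

    def fit(self, X, y):
        """Run the wrapper search on a labelled matrix (samples x genes)."""
        X, y = self._validate_data(X, y, dtype=float, ensure_min_features=2)
        dataset = ExpressionDataset(
            values=X,
            labels=np.asarray(y).astype(str),
            gene_ids=tuple(f"g{j}" for j in range(X.shape[1])),
            name="fit-input",
        )
        if self.normalize:
            dataset = minmax_normalize(dataset)
        seed = self._seed()
        trace = run_method(dataset, self.method, self._build_config(seed))
        final = trace.best_widow.evaluation
        self.support_ = np.asarray(final.mask, dtype=bool).copy()
        self.best_fitness_ = float(final.fitness)
        self.cv_error_ = float(final.error_rate)
        self.n_selected_ = int(final.n_selected)
        self.trace_ = trace
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def _validate_data(self, X, y, **kwargs):
        # sklearn >=1.6 moved validate_data to a function; keep both paths.
        try:
            from sklearn.utils.validation import validate_data

            return validate_data(self, X=X, y=y, **kwargs)
        except ImportError:  # pragma: no cover - older sklearn
            return super()._validate_data(X, y, **kwargs)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class BlackWidowSelector(BaseWrapperGeneSelector):
    """Gene selection by plain Black Widow Optimization."""

    method = "bwo"


class IteratedGreedySelector(BaseWrapperGeneSelector):
    """Gene selection by standalone Iterated Greedy from a random start."""

    method = "ig"


class HybridBWOIGSelector(BaseWrapperGeneSelector):
    """Gene selection by the BWO-IG hybrid (the recommended default)."""

    method = "bwo-ig"


def make_selector(method: str, **params) -> BaseWrapperGeneSelector:
    """Instantiate the selector class for a method name ("bwo", "ig", "bwo-ig")."""
    classes = {
        "bwo": BlackWidowSelector,
        "ig": IteratedGreedySelector,
        "bwo-ig": HybridBWOIGSelector,
    }
    if method not in classes:
        raise ValueError(
            f"unknown method {method!r}; valid methods are {', '.join(VALID_METHODS)}"
        )
    return classes[method](**params)
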