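"""Iterated Greedy refinement: destruction, greedy reconstruction, SA acceptance.

Each IG iteration removes a random sample of ``d`` currently selected
genes (destruction), then walks the removed genes in removal order and
re-selects each one only if doing so strictly lowers the wrapper fitness
(greedy construction — the subset-encoding analogue of NEH re-insertion).
The rebuilt solution replaces the incumbent if it improves it, or
otherwise with probability exp(-dE / T) under a constant temperature

    T = sum_ij P_ij / (n * m * 10)

i.e. one tenth of the mean normalized expression value — no cooling
schedule. With data min-max normalized to [0, 1], T lies in [0, 0.1],
the same order as typical fitness deltas, so the acceptance curve is
informative rather than saturated. The best solution seen is tracked
separately from the (possibly worsening) incumbent and is what the
refinement returns, so IG never degrades its input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bwo import RunTrace, Widow, _better
from .datasets import ExpressionDataset
from .fitness import WrapperFitnessEvaluator, decode_mask


@dataclass(frozen=True)
class IGConfig:
    """IG parameters.

    ``d`` fixes the destruction size; when None (default) it is
    proportional, d = max(1, round(destruct_frac * n_selected)), which
    scales across gene counts from hundreds to tens of thousands.
    ``t_scale`` multiplies the constant temperature (0 disables uphill
    acceptance). ``construct_mode`` "greedy" re-tests each removed gene
    once; "swap_aware" additionally tries exchanging it one-for-one with
    each currently selected gene, at substantially higher evaluation cost.
    """

    d: int | None = None
    destruct_frac: float = 0.2
    ig_iterations: int = 10
    t_scale: float = 1.0
    seed: int = 0
    construct_mode: str = "greedy"

    def __post_init__(self) -> None:
        if self.d is not None and self.d < 1:
            raise ValueError("d must be >= 1 when given")
        if not 0.0 < self.destruct_frac <= 1.0:
            raise ValueError("destruct_frac must lie in (0, 1]")
        if self.ig_iterations < 1:
            raise ValueError("ig_iterations must be >= 1")
        if self.t_scale < 0:
            raise ValueError("t_scale must be >= 0")
        if self.construct_mode not in ("greedy", "swap_aware"):
            raise ValueError("construct_mode must be 'greedy' or 'swap_aware'")


@dataclass(frozen=True)
class DestructionResult:
    """A partial solution plus the genes removed from it, in removal order."""

    partial: Widow
    removed: tuple[int, ...]


def compute_temperature(
    dataset: ExpressionDataset | np.ndarray, t_scale: float = 1.0
) -> float:
    """Constant SA temperature: t_scale * mean(values) / 10.

    Equivalent to summing every matrix entry and dividing by n * m * 10.
    """
    values = dataset.values if isinstance(dataset, ExpressionDataset) else np.asarray(dataset, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a temperature from an empty matrix")
    return float(t_scale * values.mean() / 10.0)


def destruct(
    solution: Widow,
    d: int,
    rng: np.random.Generator,
    lb: float = 0.0,
    threshold: float = 0.5,
) -> DestructionResult:
    """Deselect d random selected genes (capped so at least one remains).

    Removed genes have their genotype entries set to ``lb`` (below the
    decoding threshold). A solution with <= 1 selected gene cannot be
    destroyed: the original is returned with an empty removal list — a
    signal, not an error, so optimizer loops need no special-casing.
    """
    selected = np.flatnonzero(decode_mask(solution.genotype, threshold))
    if selected.size <= 1:
        return DestructionResult(partial=solution, removed=())
    d_eff = min(d, selected.size - 1)
    removed = rng.choice(selected, size=d_eff, replace=False)
    genotype = solution.genotype.copy()
    genotype[removed] = lb
    return DestructionResult(
        partial=Widow(genotype), removed=tuple(int(g) for g in removed)
    )


def construct_greedy(
    partial: Widow,
    removed: tuple[int, ...],
    evaluator: WrapperFitnessEvaluator,
    ub: float = 1.0,
    lb: float = 0.0,
    mode: str = "greedy",
) -> Widow:
    """Re-insert removed genes one at a time, keeping only strict improvements.

    For each removed gene in removal order, the candidate with that gene
    re-selected (genotype entry set to ``ub``) replaces the incumbent iff
    its fitness is strictly lower; ties favour the smaller subset, i.e.
    the incumbent. In "swap_aware" mode each removed gene is additionally
    tried as a one-for-one replacement of every currently selected gene.
    """
    incumbent = partial
    if incumbent.evaluation is None:
        incumbent.evaluation = evaluator.evaluate_genotype(incumbent.genotype)
    for gene in removed:
        genotype = incumbent.genotype.copy()
        genotype[gene] = ub
        candidate = Widow(genotype)
        candidate.evaluation = evaluator.evaluate_genotype(candidate.genotype)
        if candidate.fitness < incumbent.fitness:
            incumbent = candidate
        if mode == "swap_aware":
            for other in np.flatnonzero(decode_mask(incumbent.genotype)):
                if other == gene:
                    continue
                swapped = incumbent.genotype.copy()
                swapped[gene] = ub
                swapped[other] = lb  # deselect the exchanged gene
                cand = Widow(swapped)
                cand.evaluation = evaluator.evaluate_genotype(cand.genotype)
                if cand.fitness < incumbent.fitness:
                    incumbent = cand
    return incumbent


def accept(
    incumbent_fitness: float,
    candidate_fitness: float,
    temperature: float,
    rng: np.random.Generator,
) -> bool:
    """Constant-temperature SA acceptance.

    Improvements are always accepted. A non-improving candidate (dE =
    f(candidate) - f(incumbent) >= 0) is accepted iff a uniform draw r
    satisfies r < exp(-dE / T); at T = 0 every non-improving candidate is
    rejected.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if candidate_fitness < incumbent_fitness:
        return True
    if temperature == 0:
        return False
    delta = candidate_fitness - incumbent_fitness
    return bool(rng.random() < math.exp(-delta / temperature))


def _destruction_size(config: IGConfig, n_selected: int) -> int:
    if config.d is not None:
        return config.d
    return max(1, int(round(config.destruct_frac * n_selected)))


def run_ig(
    start: Widow,
    dataset: ExpressionDataset,
    config: IGConfig,
    evaluator: WrapperFitnessEvaluator,
    rng: np.random.Generator,
) -> tuple[Widow, RunTrace]:
    """Iterate {destruct -> greedy construct -> SA accept} from ``start``.

    The incumbent may worsen through SA acceptance; the best-so-far is
    tracked separately and returned, so the result's fitness never
    exceeds the start's. Deterministic for a fixed RNG state.
    """
    if start.evaluation is None:
        start.evaluation = evaluator.evaluate_genotype(start.genotype)
    temperature = compute_temperature(dataset, config.t_scale)
    incumbent = start
    best = start
    history = [best.fitness]
    for _ in range(config.ig_iterations):
        d = _destruction_size(config, incumbent.n_selected)
        result = destruct(incumbent, d, rng)
        if not result.removed:
            history.append(best.fitness)
            continue
        rebuilt = construct_greedy(
            result.partial, result.removed, evaluator, mode=config.construct_mode
        )
        best = _better(best, rebuilt)
        if accept(incumbent.fitness, rebuilt.fitness, temperature, rng):
            incumbent = rebuilt
        history.append(best.fitness)
    trace = RunTrace(
        best_fitness_history=history,
        best_widow=best,
        population_fitness_history=[],
        seed=config.seed,
        evaluations=evaluator.n_calls,
        method="ig",
    )
    return best, trace
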