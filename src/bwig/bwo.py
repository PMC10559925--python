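"""Black Widow Optimization for wrapper gene selection.

A population of "widows" (continuous genotypes in [LB, UB]) evolves by
pairwise procreation (per-coordinate arithmetic crossover), cannibalism
(each mating keeps only the better parent and the better child), and swap
mutation (exchange two genotype positions). Each iteration rebuilds the
population as the Nr procreation survivors plus Nm swap-mutants of
population members, with Nr = round(pr * Npop) rounded down to even and
Nm = Npop - Nr, so the population size is invariant. The incumbent best
widow W* is updated whenever any evaluated widow beats it.

Randomness is split into labelled, independently seeded streams (init,
pairing, crossover, mutation, ...) derived from one master seed, so a
hybrid runner can consume extra streams without perturbing the base
optimizer's trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .datasets import ExpressionDataset
from .fitness import EvaluatedSolution, FitnessSpec, WrapperFitnessEvaluator

STREAM_NAMES = (
    "init",
    "pairing",
    "crossover",
    "mutation",
    "ig_start",
    "ig_destruction",
    "ig_acceptance",
)


def spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent labelled RNG streams from one master seed.

    Each stream gets its own SeedSequence spawn key, so drawing from one
    stream never changes another's output — the contract that makes the
    hybrid reduce bit-exactly to plain BWO when its extra streams go unused.
    """
    return {
        name: np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        for i, name in enumerate(STREAM_NAMES)
    }


class ConfigError(ValueError):
    """An optimizer configuration violates its arithmetic closure."""


@dataclass
class Widow:
    """One candidate solution: a genotype vector plus its cached evaluation."""

    genotype: np.ndarray
    evaluation: EvaluatedSolution | None = None

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=float)

    @property
    def fitness(self) -> float:
        if self.evaluation is None:
            raise ValueError("widow has not been evaluated")
        return self.evaluation.fitness

    @property
    def n_selected(self) -> int:
        if self.evaluation is None:
            raise ValueError("widow has not been evaluated")
        return self.evaluation.n_selected


@dataclass(frozen=True)
class BWOConfig:
    """BWO loop parameters.

    Defaults follow the published tuning for microarray gene selection:
    population 10, 100 iterations, procreation rate 0.6, mutation rate
    0.4, genotype bounds [0, 1]. The closure round_even(pr*Npop) +
    round(mr*Npop) == Npop is checked at construction so the population
    size never drifts mid-run. ``procreate_repeats`` > 1 applies the
    crossover several times per pair, pooling the children before
    cannibalism. ``patience`` optionally stops early after that many
    iterations without at least ``patience_tol`` improvement of W*.
    """

    pop_size: int = 10
    max_iterations: int = 100
    pr: float = 0.6
    mr: float = 0.4
    lb: float = 0.0
    ub: float = 1.0
    seed: int = 0
    procreate_repeats: int = 1
    patience: int | None = None
    patience_tol: float = 1e-2

    def __post_init__(self) -> None:
        if not (0.0 <= self.pr <= 1.0 and 0.0 <= self.mr <= 1.0):
            raise ConfigError("pr and mr must lie in [0, 1]")
        if self.pop_size < 2:
            raise ConfigError("pop_size must be >= 2")
        if self.max_iterations < 0:
            raise ConfigError("max_iterations must be >= 0")
        if self.lb > self.ub:
            raise ConfigError("lb must not exceed ub")
        if self.procreate_repeats < 1:
            raise ConfigError("procreate_repeats must be >= 1")
        if self.n_reproduce + self.n_mutate != self.pop_size:
            raise ConfigError(
                f"population closure violated: even-rounded pr*Npop "
                f"({self.n_reproduce}) + round(mr*Npop) ({self.n_mutate}) "
                f"!= Npop ({self.pop_size})"
            )

    @property
    def n_reproduce(self) -> int:
        nr = int(round(self.pr * self.pop_size))
        return nr - (nr % 2)

    @property
    def n_mutate(self) -> int:
        return int(round(self.mr * self.pop_size))


@dataclass
class RunTrace:
    """Per-run record: best-so-far trace, final best widow, evaluation count.

    ``best_fitness_history[0]`` is the initial population's best;
    subsequent entries record W* after each iteration (non-increasing by
    construction). ``ig_invocations`` lists the iteration indices at which
    a local-search handoff fired (empty for plain BWO).
    """

    best_fitness_history: list[float]
    best_widow: Widow
    population_fitness_history: list[np.ndarray]
    seed: int
    evaluations: int
    method: str = "bwo"
    ig_invocations: list[int] = field(default_factory=list)

    @property
    def final_fitness(self) -> float:
        return self.best_fitness_history[-1]

    @property
    def iterations_to_best(self) -> int:
        """First iteration index at which the final best fitness was reached."""
        final = self.best_fitness_history[-1]
        for i, f in enumerate(self.best_fitness_history):
            if f <= final:
                return i
        return len(self.best_fitness_history) - 1

    def iterations_to_within(self, tol: float, relative: bool = False) -> int:
        """First iteration whose best fitness is within ``tol`` of the final one.

        ``tol`` is absolute on the [0, 1] fitness scale by default (the
        natural band for convergence-curve comparisons); ``relative=True``
        interprets it as a fraction of the final fitness instead.
        """
        final = self.best_fitness_history[-1]
        cutoff = final * (1.0 + tol) if relative else final + tol
        for i, f in enumerate(self.best_fitness_history):
            if f <= cutoff:
                return i
        return len(self.best_fitness_history) - 1


def init_population(
    config: BWOConfig, nvar: int, rng: np.random.Generator
) -> list[Widow]:
    """Npop widows with genotype entries uniform on [lb, ub]."""
    if nvar < 1:
        raise ValueError("nvar must be >= 1")
    return [
        Widow(rng.uniform(config.lb, config.ub, size=nvar))
        for _ in range(config.pop_size)
    ]


def selection_probability(fitness_values: Sequence[float]) -> np.ndarray:
    """Normalize raw fitness values to a probability vector, Pro_i = f_i / sum f.

    An all-zero vector (every solution perfect under a minimized
    objective) degenerates to the uniform distribution.
    """
    f = np.asarray(fitness_values, dtype=float)
    if f.size == 0:
        raise ValueError("fitness vector is empty")
    if np.any(f < 0):
        raise ValueError("fitness values must be non-negative")
    total = f.sum()
    if total == 0:
        return np.full(f.size, 1.0 / f.size)
    return f / total


def procreate(
    x1: Widow, x2: Widow, rng: np.random.Generator
) -> tuple[Widow, Widow]:
    """Arithmetic crossover: y1 = a*x1 + (1-a)*x2, y2 = a*x2 + (1-a)*x1.

    ``a`` is a fresh per-coordinate uniform [0,1) vector, one draw per
    mating. Offspring stay within the parents' bounds by convexity, and
    y1 + y2 == x1 + x2 exactly (per coordinate, to floating tolerance).
    """
    if x1.genotype.shape != x2.genotype.shape:
        raise ValueError("parent genotypes differ in length")
    alpha = rng.random(x1.genotype.shape[0])
    y1 = alpha * x1.genotype + (1.0 - alpha) * x2.genotype
    y2 = alpha * x2.genotype + (1.0 - alpha) * x1.genotype
    return Widow(y1), Widow(y2)


def _better(a: Widow, b: Widow) -> Widow:
    """Lower fitness wins; ties go to fewer selected genes, then to ``a``."""
    if b.fitness < a.fitness:
        return b
    if b.fitness == a.fitness and b.n_selected < a.n_selected:
        return b
    return a


def cannibalize_pair(
    x1: Widow, x2: Widow, y1: Widow, y2: Widow
) -> tuple[Widow, Widow]:
    """Survivor selection for one mating: keep the better parent and better child."""
    return _better(x1, x2), _better(y1, y2)


def mutate_swap(widow: Widow, rng: np.random.Generator) -> Widow:
    """Exchange the genotype values at two distinct random positions."""
    n = widow.genotype.shape[0]
    if n < 2:
        raise ValueError("swap mutation needs a genotype of length >= 2")
    i, j = rng.choice(n, size=2, replace=False)
    genotype = widow.genotype.copy()
    genotype[i], genotype[j] = genotype[j], genotype[i]
    return Widow(genotype)


def _sorted_by_fitness(population: list[Widow]) -> list[Widow]:
    order = np.argsort([w.fitness for w in population], kind="stable")
    return [population[i] for i in order]


def bwo_iteration(
    population: list[Widow],
    config: BWOConfig,
    evaluator: WrapperFitnessEvaluator,
    rng_pairing: np.random.Generator,
    rng_crossover: np.random.Generator,
    rng_mutation: np.random.Generator,
) -> tuple[list[Widow], Widow]:
    """One BWO generation: procreation + cannibalism, then swap mutation.

    ``population`` must be evaluated and sorted ascending by fitness
    (pop1). Returns the new population (size exactly Npop, all evaluated)
    and its best member.
    """
    npop = config.pop_size
    pop2: list[Widow] = []
    for _ in range(config.n_reproduce // 2):
        i, j = rng_pairing.choice(npop, size=2, replace=False)
        x1, x2 = population[i], population[j]
        children: list[Widow] = []
        for _ in range(config.procreate_repeats):
            y1, y2 = procreate(x1, x2, rng_crossover)
            children.extend((y1, y2))
        for child in children:
            child.evaluation = evaluator.evaluate_genotype(child.genotype)
        best_child = children[0]
        for child in children[1:]:
            best_child = _better(best_child, child)
        if config.procreate_repeats == 1:
            parent, child = cannibalize_pair(x1, x2, children[0], children[1])
        else:
            parent, child = _better(x1, x2), best_child
        pop2.extend((parent, child))

    pop3: list[Widow] = []
    n_mutants = npop - len(pop2)
    if n_mutants > 0:
        sources = rng_mutation.choice(npop, size=n_mutants, replace=False)
        for idx in sources:
            mutant = mutate_swap(population[idx], rng_mutation)
            mutant.evaluation = evaluator.evaluate_genotype(mutant.genotype)
            pop3.append(mutant)

    new_population = pop2 + pop3
    best = new_population[0]
    for w in new_population[1:]:
        best = _better(best, w)
    return new_population, best


RefineHook = Callable[[int, Widow], "Widow | None"]


def _bwo_loop(
    dataset: ExpressionDataset,
    config: BWOConfig,
    spec: FitnessSpec,
    *,
    evaluator: WrapperFitnessEvaluator | None = None,
    streams: dict[str, np.random.Generator] | None = None,
    refine: RefineHook | None = None,
    method: str = "bwo",
) -> RunTrace:
    """The shared BWO engine; ``refine`` lets a hybrid hand W* to local search.

    ``refine(iteration, best)`` may return an improved widow; if its
    fitness does not exceed W*'s, it replaces W* and is injected into the
    population in place of the current worst member. The hook draws only
    from its own RNG streams, so the trajectory with ``refine=None`` is
    bit-identical to a run where the hook never fires.
    """
    if evaluator is None:
        evaluator = WrapperFitnessEvaluator(dataset, spec)
    if streams is None:
        streams = spawn_streams(config.seed)

    population = init_population(config, dataset.n_genes, streams["init"])
    for w in population:
        w.evaluation = evaluator.evaluate_genotype(w.genotype)
    population = _sorted_by_fitness(population)
    best = population[0]

    trace = RunTrace(
        best_fitness_history=[best.fitness],
        best_widow=best,
        population_fitness_history=[np.array([w.fitness for w in population])],
        seed=config.seed,
        evaluations=0,
        method=method,
    )

    stall = 0
    last_improvement_ref = best.fitness
    for iteration in range(1, config.max_iterations + 1):
        population, iter_best = bwo_iteration(
            population,
            config,
            evaluator,
            streams["pairing"],
            streams["crossover"],
            streams["mutation"],
        )
        best = _better(best, iter_best)

        if refine is not None:
            refined = refine(iteration, best)
            if refined is not None:
                trace.ig_invocations.append(iteration)
                if refined.fitness <= best.fitness:
                    best = refined
                    worst_idx = int(np.argmax([w.fitness for w in population]))
                    population[worst_idx] = refined

        population = _sorted_by_fitness(population)
        trace.best_fitness_history.append(best.fitness)
        trace.population_fitness_history.append(
            np.array([w.fitness for w in population])
        )

        if config.patience is not None:
            if last_improvement_ref - best.fitness > config.patience_tol:
                stall = 0
                last_improvement_ref = best.fitness
            else:
                stall += 1
                if stall >= config.patience:
                    break

    trace.best_widow = best
    trace.evaluations = evaluator.n_calls
    return trace


def run_bwo(
    dataset: ExpressionDataset,
    config: BWOConfig,
    spec: FitnessSpec,
    *,
    evaluator: WrapperFitnessEvaluator | None = None,
) -> RunTrace:
    """Run plain BWO on a normalized dataset; deterministic for a fixed seed."""
    return _bwo_loop(dataset, config, spec, evaluator=evaluator, method="bwo")
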