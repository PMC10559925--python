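"""The BWO-IG hybrid: Iterated Greedy refinement interleaved into the BWO loop.

The hybrid runs ordinary BWO generations; every ``ig_period`` iterations
(and once more after the final iteration) the incumbent best widow W* is
handed to IG for refinement. The refined solution replaces W* whenever it
is at least as good, and is injected into the population in place of the
current worst widow so the improvement propagates into subsequent
procreation. IG draws only from its own random streams, so with the
handoff disabled the hybrid's trajectory is bit-identical to plain BWO
under the same master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bwo import (
    BWOConfig,
    ConfigError,
    RunTrace,
    Widow,
    _bwo_loop,
    init_population,
    spawn_streams,
)
from .datasets import ExpressionDataset
from .fitness import FitnessSpec, WrapperFitnessEvaluator
from .ig import IGConfig, run_ig

VALID_METHODS = ("bwo", "ig", "bwo-ig")


@dataclass(frozen=True)
class HybridConfig:
    """Configuration of the hybrid (and, via ``run_method``, of all runners).

    ``ig_period`` counts BWO iterations between IG handoffs; None disables
    interleaved refinement entirely. ``final_refine`` controls the extra
    refinement after the last iteration. ``seed`` is the master seed for
    every random stream; when None it falls back to ``bwo.seed``.
    """

    bwo: BWOConfig = field(default_factory=BWOConfig)
    ig: IGConfig = field(default_factory=IGConfig)
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    ig_period: int | None = 10
    final_refine: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ig_period is not None:
            if self.ig_period < 1:
                raise ConfigError("ig_period must be >= 1")
            if self.ig_period > self.bwo.max_iterations:
                raise ConfigError(
                    f"ig_period ({self.ig_period}) exceeds max_iterations "
                    f"({self.bwo.max_iterations})"
                )

    @property
    def master_seed(self) -> int:
        return self.bwo.seed if self.seed is None else self.seed


def run_bwo_ig(dataset: ExpressionDataset, config: HybridConfig) -> RunTrace:
    """Run the BWO-IG hybrid; returns a trace whose IG handoffs are marked.

    The trace's best-fitness history stays non-increasing across handoffs
    (IG returns its best-so-far, which never degrades its input), and
    IG's fitness evaluations are included in ``trace.evaluations``.
    """
    evaluator = WrapperFitnessEvaluator(dataset, config.fitness)
    streams = spawn_streams(config.master_seed)
    ig_rng = streams["ig_destruction"]
    accept_rng = streams["ig_acceptance"]

    def refine(iteration: int, best: Widow) -> Widow | None:
        due = (
            config.ig_period is not None and iteration % config.ig_period == 0
        ) or (config.final_refine and iteration == config.bwo.max_iterations)
        if not due:
            return None
        refined, _ = run_ig(
            best, dataset, config.ig, evaluator, _InterleavedRNG(ig_rng, accept_rng)
        )
        return refined

    trace = _bwo_loop(
        dataset,
        config.bwo,
        config.fitness,
        evaluator=evaluator,
        streams=streams,
        refine=refine if (config.ig_period is not None or config.final_refine) else None,
        method="bwo-ig",
    )
    return trace


class _InterleavedRNG:
    """Routes IG's destruction draws and acceptance draws to separate streams.

    ``run_ig`` takes a single generator; this adapter dispatches
    ``choice`` (used only by destruction) and ``random`` (used only by
    acceptance) to independently seeded streams so each sub-operator's
    sequence is stable regardless of how often the other fires.
    """

    def __init__(self, choice_rng, uniform_rng):
        self._choice_rng = choice_rng
        self._uniform_rng = uniform_rng

    def choice(self, *args, **kwargs):
        return self._choice_rng.choice(*args, **kwargs)

    def random(self, *args, **kwargs):
        return self._uniform_rng.random(*args, **kwargs)


def run_method(
    dataset: ExpressionDataset, method: str, config: HybridConfig
) -> RunTrace:
    """Dispatch to one of the runners: "bwo", "ig" or "bwo-ig".

    Standalone IG starts from a random evaluated widow drawn from the
    init stream (the same first widow plain BWO would create).
    """
    if method == "bwo":
        from .bwo import run_bwo

        bwo_cfg = config.bwo
        if config.seed is not None and bwo_cfg.seed != config.seed:
            from dataclasses import replace

            bwo_cfg = replace(bwo_cfg, seed=config.seed)
        return run_bwo(dataset, bwo_cfg, config.fitness)
    if method == "bwo-ig":
        return run_bwo_ig(dataset, config)
    if method == "ig":
        evaluator = WrapperFitnessEvaluator(dataset, config.fitness)
        streams = spawn_streams(config.master_seed)
        start = init_population(config.bwo, dataset.n_genes, streams["init"])[0]
        start.evaluation = evaluator.evaluate_genotype(start.genotype)
        _, trace = run_ig(
            start,
            dataset,
            config.ig,
            evaluator,
            _InterleavedRNG(streams["ig_destruction"], streams["ig_acceptance"]),
        )
        return trace
    raise ValueError(
        f"unknown method {method!r}; valid methods are {', '.join(VALID_METHODS)}"
    )
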