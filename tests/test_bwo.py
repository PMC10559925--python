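import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bwig import BWOConfig, FitnessSpec, WrapperFitnessEvaluator, run_bwo
from bwig.bwo import (
    ConfigError,
    Widow,
    bwo_iteration,
    cannibalize_pair,
    init_population,
    mutate_swap,
    procreate,
    selection_probability,
    spawn_streams,
)
from bwig.fitness import EvaluatedSolution, exhaustive_best_mask


def _widow(genotype, fitness=None, n_selected=None):
    w = Widow(np.asarray(genotype, dtype=float))
    if fitness is not None:
        mask = w.genotype > 0.5
        n = int(mask.sum()) if n_selected is None else n_selected
        w.evaluation = EvaluatedSolution(
            mask=mask, error_rate=fitness, n_selected=n, fitness=fitness
        )
    return w


class _ForcedRng:
    """Deterministic stand-in: returns pre-set uniforms and index choices."""

    def __init__(self, uniforms=None, choices=None):
        self._uniforms = list(uniforms or [])
        self._choices = list(choices or [])

    def random(self, n=None):
        out = self._uniforms.pop(0)
        return np.asarray(out) if n is not None else out

    def choice(self, n, size=None, replace=True):
        return np.asarray(self._choices.pop(0))


class TestConfig:
    def test_default_closure(self):
        cfg = BWOConfig()
        assert cfg.n_reproduce == 6 and cfg.n_mutate == 4

    def test_closure_violation_raises_at_construction(self):
        with pytest.raises(ConfigError, match="closure"):
            BWOConfig(pop_size=10, pr=0.5, mr=0.2)

    def test_pr_one_gives_all_procreation(self):
        cfg = BWOConfig(pop_size=10, pr=1.0, mr=0.0)
        assert cfg.n_reproduce == 10 and cfg.n_mutate == 0


class TestInitPopulation:
    def test_bounds_and_size(self):
        rng = np.random.default_rng(0)
        pop = init_population(BWOConfig(), nvar=100, rng=rng)
        assert len(pop) == 10
        for w in pop:
            assert w.genotype.shape == (100,)
            assert np.all((w.genotype >= 0) & (w.genotype <= 1))

    def test_degenerate_bounds(self):
        cfg = BWOConfig(lb=0.7, ub=0.7)
        pop = init_population(cfg, nvar=5, rng=np.random.default_rng(0))
        for w in pop:
            np.testing.assert_allclose(w.genotype, 0.7)

    def test_seed_determinism(self):
        a = init_population(BWOConfig(), 20, np.random.default_rng(3))
        b = init_population(BWOConfig(), 20, np.random.default_rng(3))
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.genotype, wb.genotype)


class TestSelectionProbability:
    @pytest.mark.parametrize(
        "fitness,expected",
        [
            ([2.0], [1.0]),
            ([1.0, 1.0, 2.0], [0.25, 0.25, 0.5]),
            ([0.1, 0.3, 0.6], [0.1, 0.3, 0.6]),
        ],
    )
    def test_normalization(self, fitness, expected):
        np.testing.assert_allclose(selection_probability(fitness), expected)

    def test_all_zero_degenerates_to_uniform(self):
        np.testing.assert_allclose(selection_probability([0.0, 0.0]), [0.5, 0.5])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            selection_probability([0.5, -0.1])


class TestProcreate:
    def test_forced_alpha_identity_and_swap(self):
        x1, x2 = _widow([0.0, 1.0]), _widow([1.0, 0.0])
        y1, y2 = procreate(x1, x2, _ForcedRng(uniforms=[[1.0, 1.0]]))
        np.testing.assert_array_equal(y1.genotype, x1.genotype)
        np.testing.assert_array_equal(y2.genotype, x2.genotype)
        y1, y2 = procreate(x1, x2, _ForcedRng(uniforms=[[0.0, 0.0]]))
        np.testing.assert_array_equal(y1.genotype, x2.genotype)
        np.testing.assert_array_equal(y2.genotype, x1.genotype)

    def test_forced_alpha_midpoint(self):
        y1, y2 = procreate(
            _widow([0.0, 1.0]), _widow([1.0, 0.0]), _ForcedRng(uniforms=[[0.5, 0.5]])
        )
        np.testing.assert_allclose(y1.genotype, [0.5, 0.5])
        np.testing.assert_allclose(y2.genotype, [0.5, 0.5])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            procreate(_widow([0.1]), _widow([0.1, 0.2]), np.random.default_rng(0))

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_conservation_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x1, x2 = _widow(rng.random(30)), _widow(rng.random(30))
        y1, y2 = procreate(x1, x2, rng)
        np.testing.assert_allclose(
            y1.genotype + y2.genotype, x1.genotype + x2.genotype, atol=1e-12
        )
        lo = np.minimum(x1.genotype, x2.genotype) - 1e-12
        hi = np.maximum(x1.genotype, x2.genotype) + 1e-12
        for y in (y1, y2):
            assert np.all((y.genotype >= lo) & (y.genotype <= hi))


class TestCannibalism:
    def test_better_parent_and_child_survive(self):
        x1, x2 = _widow([1, 0, 0], 0.2), _widow([0, 1, 0], 0.5)
        y1, y2 = _widow([1, 1, 0], 0.3), _widow([0, 0, 1], 0.1)
        p, c = cannibalize_pair(x1, x2, y1, y2)
        assert p is x1 and c is y2

    def test_all_equal_keeps_first_arguments(self):
        ws = [_widow([1.0, 0.0], 0.4) for _ in range(4)]
        p, c = cannibalize_pair(*ws)
        assert p is ws[0] and c is ws[2]

    def test_fitness_tie_broken_by_subset_size(self):
        x1 = _widow([1, 1, 1], 0.4, n_selected=3)
        x2 = _widow([1, 0, 0], 0.4, n_selected=1)
        y1, y2 = _widow([1, 1, 0], 0.5), _widow([0, 1, 1], 0.6)
        p, _ = cannibalize_pair(x1, x2, y1, y2)
        assert p is x2


class TestMutateSwap:
    def test_forced_positions(self):
        out = mutate_swap(_widow([1, 2, 3, 4]), _ForcedRng(choices=[[0, 3]]))
        np.testing.assert_array_equal(out.genotype, [4, 2, 3, 1])

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_multiset_preserved(self, seed):
        rng = np.random.default_rng(seed)
        w = _widow(rng.random(12))
        out = mutate_swap(w, rng)
        np.testing.assert_array_equal(
            np.sort(out.genotype), np.sort(w.genotype)
        )

    def test_length_one_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            mutate_swap(_widow([0.4]), np.random.default_rng(0))


class TestIterationStructure:
    def _evaluated_population(self, evaluator, cfg, nvar, seed=0):
        pop = init_population(cfg, nvar, np.random.default_rng(seed))
        for w in pop:
            w.evaluation = evaluator.evaluate_genotype(w.genotype)
        return sorted(pop, key=lambda w: w.fitness)

    def test_population_size_closure(self, tiny_evaluator):
        cfg = BWOConfig()
        pop = self._evaluated_population(tiny_evaluator, cfg, 8)
        streams = spawn_streams(0)
        new_pop, best = bwo_iteration(
            pop, cfg, tiny_evaluator, streams["pairing"], streams["crossover"], streams["mutation"]
        )
        assert len(new_pop) == 10
        assert all(w.evaluation is not None for w in new_pop)
        assert best.fitness == min(w.fitness for w in new_pop)

    def test_pr_one_all_from_procreation(self, tiny_evaluator):
        cfg = BWOConfig(pr=1.0, mr=0.0)
        pop = self._evaluated_population(tiny_evaluator, cfg, 8)
        streams = spawn_streams(1)
        new_pop, _ = bwo_iteration(
            pop, cfg, tiny_evaluator, streams["pairing"], streams["crossover"], streams["mutation"]
        )
        assert len(new_pop) == 10

    def test_size_invariant_under_constant_objective(self, tiny_sep):
        ds, _ = tiny_sep

        class _Const:
            n_calls = 0

            def evaluate_genotype(self, g):
                self.n_calls += 1
                mask = g > 0.5
                return EvaluatedSolution(
                    mask=mask, error_rate=0.5, n_selected=int(mask.sum()), fitness=0.5
                )

        cfg = BWOConfig()
        ev = _Const()
        pop = init_population(cfg, 8, np.random.default_rng(2))
        for w in pop:
            w.evaluation = ev.evaluate_genotype(w.genotype)
        streams = spawn_streams(2)
        new_pop, _ = bwo_iteration(
            pop, cfg, ev, streams["pairing"], streams["crossover"], streams["mutation"]
        )
        assert len(new_pop) == 10


class TestRunBwo:
    def test_trace_invariants_across_seeds(self, small_synth):
        ds, _ = small_synth
        spec = FitnessSpec(cv_folds=5, cv_seed=0)
        for seed in range(5):
            trace = run_bwo(ds, BWOConfig(seed=seed, max_iterations=15), spec)
            hist = np.array(trace.best_fitness_history)
            assert len(hist) == 16
            assert np.all(np.diff(hist) <= 0)
            assert trace.best_widow.fitness == hist[-1]

    def test_zero_iterations_keeps_initial_best(self, tiny_sep, loocv_spec):
        ds, _ = tiny_sep
        trace = run_bwo(ds, BWOConfig(seed=1, max_iterations=0), loocv_spec)
        assert len(trace.best_fitness_history) == 1

    def test_seed_determinism(self, tiny_sep, loocv_spec):
        ds, _ = tiny_sep
        a = run_bwo(ds, BWOConfig(seed=9, max_iterations=10), loocv_spec)
        b = run_bwo(ds, BWOConfig(seed=9, max_iterations=10), loocv_spec)
        assert a.best_fitness_history == b.best_fitness_history
        np.testing.assert_array_equal(a.best_widow.genotype, b.best_widow.genotype)

    def test_finds_exhaustive_optimum_often(self, tiny_sep, loocv_spec, tiny_evaluator):
        ds, _ = tiny_sep
        optimum = exhaustive_best_mask(tiny_evaluator).fitness
        hits = 0
        for seed in range(5):
            trace = run_bwo(ds, BWOConfig(seed=seed, max_iterations=60), loocv_spec)
            assert trace.final_fitness >= optimum - 1e-12  # oracle lower-bounds
            hits += trace.final_fitness <= optimum + 1e-12
        assert hits >= 3

    def test_genotypes_stay_in_bounds(self, small_synth):
        ds, _ = small_synth
        spec = FitnessSpec(cv_folds=5, cv_seed=1)
        trace = run_bwo(ds, BWOConfig(seed=4, max_iterations=10), spec)
        g = trace.best_widow.genotype
        assert np.all((g >= 0) & (g <= 1))

    def test_patience_stops_early(self, small_synth):
        ds, _ = small_synth
        spec = FitnessSpec(cv_folds=5, cv_seed=2)
        trace = run_bwo(
            ds, BWOConfig(seed=0, max_iterations=100, patience=3, patience_tol=1.0), spec
        )
        # tolerance 1.0 can never be beaten, so the run stops after 3 stalls
        assert len(trace.best_fitness_history) == 4
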