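"""Population dynamics: tournament selection, FIFO aging, evolution loop."""

import numpy as np
import pytest

from xcevolve.equivalence import EquivalenceCache
from xcevolve.evolution import (
    EvolutionConfig,
    Individual,
    Population,
    run_evolution,
    tournament_select,
)
from xcevolve.programs import empty_functional
from xcevolve.synth import b97_demo_fixture


def _individual(j_val: float) -> Individual:
    return Individual(functional=empty_functional(), params={}, j_train=j_val,
                      j_val=j_val)


@pytest.fixture(scope="module")
def tiny_run():
    """A short, seeded evolution on a small synthetic dataset."""
    fx = b97_demo_fixture(seed=5, n_systems=8, points_per_system=8,
                          n_datapoints=40)
    from dataclasses import replace
    evo = replace(fx.evolution_config, budget=150, population_size=20,
                  tournament_size=5)
    fit = replace(fx.fit_config, n_restarts=2, max_evals=300)
    result = run_evolution(fx.initial, fx.dataset, fx.mutation_config, fit, evo)
    return fx, evo, fit, result


class TestPopulation:
    def test_fifo_eviction_order(self):
        pop = Population(max_size=3)
        inds = [_individual(float(i)) for i in range(5)]
        evicted = [pop.insert(i) for i in inds]
        assert evicted[:3] == [None, None, None]
        assert evicted[3] is inds[0] and evicted[4] is inds[1]
        assert list(pop) == inds[2:]

    def test_aging_no_individual_outlives_max_size_insertions(self):
        pop = Population(max_size=10)
        first = _individual(0.0)      # best fitness forever
        pop.insert(first)
        for i in range(10):
            pop.insert(_individual(100.0 + i))
        assert first not in list(pop)

    def test_unfit_individual_ranks_below_everything(self):
        unfit = _individual(float("inf"))
        fit = _individual(1e6)
        assert unfit.fitness == -np.inf
        pop = Population(5)
        pop.insert(unfit)
        pop.insert(fit)
        assert pop.best() is fit


class TestTournament:
    def test_full_tournament_returns_global_argmax(self):
        pop = Population(10)
        for j in (5.0, 3.0, 9.0):
            pop.insert(_individual(j))
        rng = np.random.default_rng(0)
        winner = tournament_select(pop, 3, rng)
        assert winner.j_val == 3.0

    def test_singleton_tournament_is_uniform(self):
        pop = Population(10)
        for j in (5.0, 3.0, 9.0):
            pop.insert(_individual(j))
        rng = np.random.default_rng(1)
        seen = {tournament_select(pop, 1, rng).j_val for _ in range(200)}
        assert seen == {5.0, 3.0, 9.0}

    def test_oversized_tournament_is_clamped(self):
        pop = Population(10)
        pop.insert(_individual(2.0))
        winner = tournament_select(pop, 25, np.random.default_rng(0))
        assert winner.j_val == 2.0

    def test_ties_break_towards_recency(self):
        pop = Population(10)
        a, b = _individual(1.0), _individual(1.0)
        pop.insert(a)
        pop.insert(b)
        winner = tournament_select(pop, 2, np.random.default_rng(0))
        assert winner is b

    def test_selection_pressure_beats_population_mean(self):
        rng = np.random.default_rng(42)
        pop = Population(100)
        jvals = rng.uniform(1, 100, 100)
        for j in jvals:
            pop.insert(_individual(float(j)))
        mean_fitness = np.mean([i.fitness for i in pop])
        selected = [tournament_select(pop, 25, rng).fitness
                    for _ in range(1000)]
        assert np.mean(selected) >= mean_fitness

    def test_empty_population_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            tournament_select(Population(5), 3, np.random.default_rng(0))


class TestRunEvolution:
    def test_zero_budget_returns_fitted_initial(self):
        fx = b97_demo_fixture(seed=0, n_systems=4, points_per_system=4,
                              n_datapoints=12)
        from dataclasses import replace
        evo = replace(fx.evolution_config, budget=0)
        res = run_evolution(fx.initial, fx.dataset, fx.mutation_config,
                            fx.fit_config, evo)
        assert res.history == []
        assert len(res.population) == 1

    def test_population_respects_cap_and_counts_steps(self, tiny_run):
        fx, evo, fit, result = tiny_run
        assert len(result.population) <= evo.population_size
        assert len(result.history) == evo.budget

    def test_cumulative_minimum_validation_error_is_nonincreasing(self,
                                                                  tiny_run):
        _, _, _, result = tiny_run
        js = [h["j_val"] for h in result.history]
        cummin = np.minimum.accumulate(js)
        assert np.all(np.diff(cummin) <= 0)
        assert result.best.j_val == pytest.approx(np.nanmin(js))

    def test_cache_hits_skip_the_optimizer_but_still_insert(self, tiny_run):
        _, _, _, result = tiny_run
        hits = [h for h in result.history if h["cache_hit"]]
        assert hits, "a 150-step run in a tiny space must revisit forms"
        assert len(result.history) == sum(1 for _ in result.history)

    def test_single_worker_reruns_are_bit_reproducible(self):
        fx = b97_demo_fixture(seed=2, n_systems=4, points_per_system=4,
                              n_datapoints=12)
        from dataclasses import replace
        evo = replace(fx.evolution_config, budget=40, population_size=10,
                      tournament_size=3)
        fit = replace(fx.fit_config, n_restarts=1, max_evals=120)
        runs = []
        for _ in range(2):
            res = run_evolution(fx.initial, fx.dataset, fx.mutation_config,
                                fit, evo)
            runs.append([(h["j_train"], h["j_val"], h["expression"]["x"])
                         for h in res.history])
        assert runs[0] == runs[1]

    def test_parallel_round_mode_keeps_size_and_eviction_semantics(self):
        fx = b97_demo_fixture(seed=2, n_systems=4, points_per_system=4,
                              n_datapoints=12)
        from dataclasses import replace
        evo = replace(fx.evolution_config, budget=60, population_size=12,
                      tournament_size=3, workers=4)
        fit = replace(fx.fit_config, n_restarts=1, max_evals=120)
        res = run_evolution(fx.initial, fx.dataset, fx.mutation_config,
                            fit, evo)
        assert len(res.history) == 60
        assert len(res.population) == 12
        indices = [i.insertion_index for i in res.population]
        assert indices == sorted(indices)          # FIFO order preserved
        assert indices[-1] == 60                   # one insertion per step

    def test_stop_callback_halts_the_run(self):
        fx = b97_demo_fixture(seed=2, n_systems=4, points_per_system=4,
                              n_datapoints=12)
        from dataclasses import replace
        evo = replace(fx.evolution_config, budget=100, population_size=10,
                      tournament_size=3)
        fit = replace(fx.fit_config, n_restarts=1, max_evals=120)
        res = run_evolution(fx.initial, fx.dataset, fx.mutation_config,
                            fit, evo, stop=lambda ind, step: step >= 7)
        assert res.stopped_at == 7
        assert len(res.history) == 7

    def test_history_jsonl_is_appended(self, tmp_path):
        import json
        fx = b97_demo_fixture(seed=2, n_systems=4, points_per_system=4,
                              n_datapoints=12)
        from dataclasses import replace
        evo = replace(fx.evolution_config, budget=10, population_size=5,
                      tournament_size=2)
        fit = replace(fx.fit_config, n_restarts=1, max_evals=120)
        path = tmp_path / "history.jsonl"
        run_evolution(fx.initial, fx.dataset, fx.mutation_config, fit, evo,
                      history_path=path)
        lines = [json.loads(l) for l in path.read_text().splitlines()]
        assert len(lines) == 10
        assert {"step", "j_train", "j_val", "expression"} <= set(lines[0])
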