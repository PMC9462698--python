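"""Regularized evolution over symbolic functionals.

A bounded FIFO population of fitted functionals is evolved by repeating:
sample a tournament subset, take its fittest member as parent, mutate one
channel by one rule, fit the child's scalar parameters on the training
split (unless an equivalent form is already cached), score it as
``fitness = -J_validation`` (kcal/mol, negated) and append it; once the
population exceeds its cap, the *oldest* member is evicted — aging, the
trait that distinguishes regularized evolution from worst-removal genetic
algorithms.  Children whose evaluation is invalid are still inserted, with
fitness ``-inf``, so the aging clock stays faithful.

``workers > 1`` reproduces the asynchronous-insertion contract of a
distributed search locally: each round selects and evaluates ``workers``
children against one population snapshot, then applies their insertions
(and evictions) atomically in order.  ``workers = 1`` is bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .equivalence import (
    CacheRecord,
    EquivalenceCache,
    ProbeSpec,
    functional_fingerprint,
)
from .fitting import DatasetEvaluator, EnergyDataset, FitConfig
from .functionals import DEFAULT_LDA, LdaKernel
from .mutation import MutationConfig, mutate_functional
from .programs import CHANNELS, SymbolicFunctional, render_expression

__all__ = [
    "Individual",
    "Population",
    "EvolutionConfig",
    "EvolutionResult",
    "tournament_select",
    "evolve_step",
    "run_evolution",
]


@dataclass
class Individual:
    functional: SymbolicFunctional
    params: dict[str, float]
    j_train: float
    j_val: float
    insertion_index: int = -1
    provenance: dict = field(default_factory=dict)

    @property
    def fitness(self) -> float:
        """Negative validation error; worst-case for invalid evaluations."""
        return -self.j_val if np.isfinite(self.j_val) else -np.inf

    def expression(self) -> dict[str, str]:
        return {ch: render_expression(self.functional.programs[ch])
                for ch in CHANNELS}


class Population:
    """Bounded FIFO queue: insertion order is eviction order."""

    def __init__(self, max_size: int = 100):
        if max_size < 1:
            raise ValueError("max_size must be positive")
        self.max_size = max_size
        self.members: deque[Individual] = deque()
        self._counter = 0

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def insert(self, ind: Individual) -> Individual | None:
        """Append; return the evicted (oldest) member if the cap is exceeded."""
        ind.insertion_index = self._counter
        self._counter += 1
        self.members.append(ind)
        if len(self.members) > self.max_size:
            return self.members.popleft()
        return None

    def best(self) -> Individual:
        return max(self.members, key=lambda i: (i.fitness, i.insertion_index))


def tournament_select(
    population: Population,
    tournament_size: int,
    rng: np.random.Generator,
) -> Individual:
    """Fittest of a uniform without-replacement sample; ties go to the
    most recently inserted."""
    n = len(population)
    if n == 0:
        raise ValueError("empty population")
    k = min(tournament_size, n)
    members = list(population.members)
    idx = rng.choice(n, size=k, replace=False)
    chosen = [members[i] for i in idx]
    return max(chosen, key=lambda i: (i.fitness, i.insertion_index))


@dataclass(frozen=True)
class EvolutionConfig:
    population_size: int = 100
    tournament_size: int = 25
    budget: int = 1000            # number of mutations (one insertion each)
    workers: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.tournament_size < 1:
            raise ValueError("population_size and tournament_size must be >= 1")
        if self.budget < 0 or self.workers < 1:
            raise ValueError("budget must be >= 0 and workers >= 1")


@dataclass
class EvolutionResult:
    best: Individual
    population: Population
    history: list[dict]
    cache: EquivalenceCache
    stopped_at: int | None = None   # step index where the stop callback fired


def _fit_child(
    child: SymbolicFunctional,
    evaluator: DatasetEvaluator,
    fit_config: FitConfig,
    cache: EquivalenceCache,
    probe_spec: ProbeSpec,
    rng: np.random.Generator,
) -> tuple[dict[str, float], float, float, bool, str]:
    """(params, J_train, J_val, cache_hit, digest); caches the fit on a miss."""
    fp = functional_fingerprint(child, probe_spec)
    record = cache.lookup(fp.digest)
    if record is not None:
        params = {p: 0.0 for p in child.parameter_names}
        params.update(record.params_for(fp))
        return params, record.j_train, record.j_val, True, fp.digest
    result = evaluator.fit(child, fit_config, rng)
    j_val = float(evaluator.split_wrmsd(child, result.params, "validation"))
    expr = " | ".join(
        render_expression(child.programs[ch]) for ch in CHANNELS
    )
    cache.insert(fp.digest, CacheRecord(
        param_values=tuple(result.params.get(n, 0.0) for n in fp.param_order),
        j_train=result.j_train, j_val=j_val, expression=expr,
    ))
    return result.params, result.j_train, j_val, False, fp.digest


def evolve_step(
    population: Population,
    evaluator: DatasetEvaluator,
    mutation_config: MutationConfig,
    fit_config: FitConfig,
    cache: EquivalenceCache,
    rng: np.random.Generator,
    tournament_size: int,
    probe_spec: ProbeSpec = ProbeSpec(),
) -> Individual:
    """One mutate -> fit -> evaluate -> insert iteration (exactly one insertion)."""
    parent = tournament_select(population, tournament_size, rng)
    child, record = mutate_functional(parent.functional, mutation_config, rng)
    params, j_train, j_val, hit, digest = _fit_child(
        child, evaluator, fit_config, cache, probe_spec, rng)
    ind = Individual(
        functional=child, params=params, j_train=j_train, j_val=j_val,
        provenance={"parent": parent.insertion_index, "channel": record.channel,
                    "rule": record.rule, "noop": record.noop, "cache_hit": hit,
                    "digest": digest},
    )
    population.insert(ind)
    return ind


def run_evolution(
    initial: SymbolicFunctional | Sequence[SymbolicFunctional],
    dataset: EnergyDataset,
    mutation_config: MutationConfig,
    fit_config: FitConfig,
    evolution_config: EvolutionConfig,
    lda: LdaKernel = DEFAULT_LDA,
    cache: EquivalenceCache | None = None,
    probe_spec: ProbeSpec = ProbeSpec(),
    stop: Callable[[Individual, int], bool] | None = None,
    history_path=None,
    population: Population | None = None,
) -> EvolutionResult:
    """Run regularized evolution for ``budget`` mutations.

    ``initial`` seeds the population (each seed is fitted first); the
    history records every evaluated form.  ``stop(individual, step)`` may
    end the run early (e.g. when a target form has been found).  Passing a
    ``population``/``cache`` continues a previous run.
    """
    rng = np.random.default_rng(evolution_config.seed)
    evaluator = DatasetEvaluator(dataset, lda)
    cache = cache if cache is not None else EquivalenceCache()
    history: list[dict] = []
    writer = open(history_path, "a") if history_path is not None else None
    best_ever: Individual | None = None

    def consider(ind: Individual) -> None:
        nonlocal best_ever
        if best_ever is None or ind.fitness >= best_ever.fitness:
            best_ever = ind

    def log(step: int, ind: Individual) -> None:
        rec = {
            "step": step,
            "j_train": ind.j_train,
            "j_val": ind.j_val,
            "fitness": ind.fitness,
            "n_instructions": {
                ch: len(ind.functional.programs[ch].instructions) for ch in CHANNELS
            },
            "expression": ind.expression(),
            **ind.provenance,
        }
        history.append(rec)
        if writer is not None:
            writer.write(json.dumps(rec) + "\n")

    if population is None:
        population = Population(evolution_config.population_size)
        seeds = [initial] if isinstance(initial, SymbolicFunctional) else list(initial)
        for fun in seeds:
            params, j_train, j_val, hit, digest = _fit_child(
                fun, evaluator, fit_config, cache, probe_spec, rng)
            population.insert(Individual(
                functional=fun, params=params, j_train=j_train, j_val=j_val,
                provenance={"parent": None, "channel": None, "rule": None,
                            "noop": False, "cache_hit": hit, "digest": digest},
            ))
            consider(population.members[-1])

    stopped_at = None
    step = 0
    try:
        while step < evolution_config.budget:
            snapshot_rng = rng
            batch = min(evolution_config.workers, evolution_config.budget - step)
            if batch == 1:
                step += 1
                ind = evolve_step(
                    population, evaluator, mutation_config, fit_config,
                    cache, snapshot_rng, evolution_config.tournament_size,
                    probe_spec,
                )
                consider(ind)
                log(step, ind)
                if stop is not None and stop(ind, step):
                    stopped_at = step
                    break
            else:
                # asynchronous contract: all parents of this round are chosen
                # against the same population snapshot, inserts are atomic
                frozen = Population(population.max_size)
                frozen.members = deque(population.members)
                frozen._counter = population._counter
                children = []
                for _ in range(batch):
                    parent = tournament_select(
                        frozen, evolution_config.tournament_size, snapshot_rng)
                    child, rec = mutate_functional(
                        parent.functional, mutation_config, snapshot_rng)
                    children.append((parent, child, rec))
                done = False
                for parent, child, rec in children:
                    step += 1
                    params, j_train, j_val, hit, digest = _fit_child(
                        child, evaluator, fit_config, cache, probe_spec,
                        snapshot_rng)
                    ind = Individual(
                        functional=child, params=params, j_train=j_train,
                        j_val=j_val,
                        provenance={"parent": parent.insertion_index,
                                    "channel": rec.channel, "rule": rec.rule,
                                    "noop": rec.noop, "cache_hit": hit,
                                    "digest": digest},
                    )
                    population.insert(ind)
                    consider(ind)
                    log(step, ind)
                    if stop is not None and stop(ind, step):
                        stopped_at = step
                        done = True
                        break
                if done:
                    break
    finally:
        if writer is not None:
            writer.close()

    if best_ever is None:
        best_ever = population.best()
    return EvolutionResult(
        best=best_ever, population=population, history=history,
        cache=cache, stopped_at=stopped_at,
    )
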