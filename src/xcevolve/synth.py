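"""Synthetic grids, systems and energetic datasets.

Real training data for functional searches consists of molecular
quadrature grids (densities evaluated once with a fixed reference
functional) and thousands of typed, weighted energy differences.  Neither
is reproducible at a desk, so this module generates data with the same
*statistical structure*: pseudo-random grids with positive densities,
log-uniform reduced-gradient features and a bounded kinetic-energy-density
feature, plus data points formed as signed combinations of system energies
whose references are computed from a chosen ground-truth functional.  With
zero noise, fitting the ground-truth form to its own dataset is exactly
solvable — which is what makes rediscovery experiments well-posed.

The default condition numbers are desk-scale: a few dozen systems of a few
dozen grid points and a few hundred data points, split 60/20/20 into
train/validation/test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .evolution import EvolutionConfig
from .fitting import (
    DEFAULT_TYPE_WEIGHTS,
    DataPoint,
    EnergyDataset,
    FitConfig,
    SPLITS,
)
from .functionals import (
    DEFAULT_LDA,
    HARTREE_TO_KCAL,
    B97_PARAMS,
    GridSystem,
    LdaKernel,
    b97_program,
    exc_semilocal,
)
from .mutation import MutationConfig
from .programs import InstructionProgram, Symbol, SymbolicFunctional

__all__ = [
    "SyntheticSpec",
    "DemoFixture",
    "generate_systems",
    "generate_dataset",
    "b97_demo_fixture",
    "b97_ground_truth",
    "run_b97_rediscovery",
    "dataset_scale",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape of the generated data; defaults are the desk-scale conditions."""

    n_systems: int = 24
    points_per_system: int = 32
    rho_range: tuple[float, float] = (1e-2, 10.0)      # log-uniform (a.u.)
    x2_range: tuple[float, float] = (1e-4, 1e4)        # log-uniform
    w_range: tuple[float, float] = (-1.0, 1.0)         # uniform
    n_datapoints: int = 300
    #: fractions of single-energy, pairwise-difference and multi-term points
    datapoint_recipe: Mapping[str, float] = field(
        default_factory=lambda: {"single": 0.2, "pair": 0.6, "multi": 0.2}
    )
    #: data-type label per recipe kind
    type_labels: Mapping[str, str] = field(
        default_factory=lambda: {"single": "AE18", "pair": "TCE", "multi": "NCE"}
    )
    type_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS)
    )
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    noise_sd: float = 0.0          # kcal/mol, on reference values
    offset_sd: float = 0.0         # kcal/mol, per-system non-XC offset
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.datapoint_recipe.values()), 1.0):
            raise ValueError("datapoint recipe fractions must sum to 1")
        if not np.isclose(sum(self.split_fractions), 1.0):
            raise ValueError("split fractions must sum to 1")
        if self.n_systems < 2 or self.points_per_system < 1:
            raise ValueError("need at least two systems with grid points")


def generate_systems(spec: SyntheticSpec) -> dict[str, GridSystem]:
    """Seeded, reproducible grids with positive densities and weights."""
    rng = np.random.default_rng([spec.seed, 101])
    systems = {}
    n = spec.points_per_system
    for i in range(spec.n_systems):
        label = f"sys{i:03d}"
        rho = 10.0 ** rng.uniform(np.log10(spec.rho_range[0]),
                                  np.log10(spec.rho_range[1]), n)
        x2 = 10.0 ** rng.uniform(np.log10(spec.x2_range[0]),
                                 np.log10(spec.x2_range[1]), n)
        w = rng.uniform(*spec.w_range, n)
        quad = rng.uniform(0.0, 2.0 / n, n)   # total volume ~ 1 a.u.
        systems[label] = GridSystem(label=label, rho=rho, x2=x2, w=w,
                                    quad_weights=quad)
    return systems


def generate_dataset(
    spec: SyntheticSpec,
    ground_truth: SymbolicFunctional,
    ground_params: Mapping[str, float],
    lda: LdaKernel = DEFAULT_LDA,
) -> EnergyDataset:
    """Reference energies from the ground-truth functional, split 60/20/20.

    Data points follow the recipe: single system energies, pairwise
    differences, and three-term signed combinations; each carries the
    per-type sample weight of its label.  Noise (if any) is Gaussian on the
    reference values.
    """
    systems = generate_systems(spec)
    rng = np.random.default_rng([spec.seed, 202])
    noise_rng = np.random.default_rng([spec.seed, 303])  # keeps structure
    # independent of the noise setting
    labels = list(systems)
    offsets = {l: float(rng.normal(0.0, spec.offset_sd)) if spec.offset_sd else 0.0
               for l in labels}
    energies = {}
    for l in labels:
        e, ok = exc_semilocal(systems[l], ground_truth, ground_params, lda,
                              return_valid=True)
        if not ok:
            raise ValueError(f"ground truth not evaluable on system {l}")
        energies[l] = offsets[l] + HARTREE_TO_KCAL * e

    kinds = list(spec.datapoint_recipe)
    counts = np.floor(np.array([spec.datapoint_recipe[k] for k in kinds])
                      * spec.n_datapoints).astype(int)
    counts[0] += spec.n_datapoints - counts.sum()
    datapoints = []
    i = 0
    for kind, count in zip(kinds, counts):
        dtype = spec.type_labels[kind]
        weight = spec.type_weights.get(dtype, 1.0)
        for _ in range(count):
            if kind == "single":
                terms = ((labels[int(rng.integers(len(labels)))], 1.0),)
            elif kind == "pair":
                a, b = rng.choice(len(labels), size=2, replace=False)
                terms = ((labels[int(a)], 1.0), (labels[int(b)], -1.0))
            else:
                picks = rng.choice(len(labels), size=3, replace=False)
                coeffs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=3)
                terms = tuple((labels[int(p)], float(c))
                              for p, c in zip(picks, coeffs))
            ref = sum(c * energies[l] for l, c in terms)
            if spec.noise_sd:
                ref += float(noise_rng.normal(0.0, spec.noise_sd))
            datapoints.append(DataPoint(
                id=f"dp{i:04d}", terms=terms, reference=float(ref),
                data_type=dtype, weight=weight,
            ))
            i += 1

    order = rng.permutation(len(datapoints))
    n_train = int(round(spec.split_fractions[0] * len(datapoints)))
    n_val = int(round(spec.split_fractions[1] * len(datapoints)))
    splits = {
        "train": [datapoints[j] for j in order[:n_train]],
        "validation": [datapoints[j] for j in order[n_train:n_train + n_val]],
        "test": [datapoints[j] for j in order[n_train + n_val:]],
    }
    return EnergyDataset(systems=systems, splits=splits, offsets=offsets)


def dataset_scale(dataset: EnergyDataset) -> float:
    """Root-mean-square reference magnitude (kcal/mol) across all splits."""
    refs = [dp.reference for name in SPLITS for dp in dataset.splits[name]]
    return float(np.sqrt(np.mean(np.square(refs))))


def b97_ground_truth() -> tuple[SymbolicFunctional, dict[str, float]]:
    """Exchange-only ground truth: the published B97 gradient correction.

    Correlation channels are empty (zero), so reference energies probe the
    exchange enhancement factor alone.
    """
    empty_ws = (Symbol("x2", "feature"), Symbol("F", "variable"))
    functional = SymbolicFunctional({
        "x": b97_program(),
        "css": InstructionProgram(workspace=empty_ws),
        "cos": InstructionProgram(workspace=empty_ws),
    })
    return functional, dict(B97_PARAMS)


@dataclass
class DemoFixture:
    """Everything needed to run the from-scratch rediscovery experiment."""

    dataset: EnergyDataset
    ground_truth: SymbolicFunctional
    ground_params: dict[str, float]
    initial: SymbolicFunctional
    mutation_config: MutationConfig
    fit_config: FitConfig
    evolution_config: EvolutionConfig
    scale: float


def b97_demo_fixture(
    seed: int = 1,
    n_systems: int = 64,
    points_per_system: int = 32,
    n_datapoints: int = 400,
    budget: int = 4000,
) -> DemoFixture:
    """The from-scratch rediscovery setting on synthetic data.

    Search space: the four-operation set {add, multiply-accumulate, square,
    finite-domain transform}, at most six instructions, workspace of one
    feature (x2), four parameters and three variables; tournament size 10,
    population 100; reference energies generated from the B97 exchange
    form.  The initial functional contains no instructions and constantly
    outputs zero.
    """
    # thermochemistry data points are reaction energies: signed combinations
    # of two or more system energies, never raw single-system energies
    spec = SyntheticSpec(
        n_systems=n_systems,
        points_per_system=points_per_system,
        n_datapoints=n_datapoints,
        datapoint_recipe={"single": 0.0, "pair": 0.7, "multi": 0.3},
        type_labels={"single": "TCE", "pair": "TCE", "multi": "TCE"},
        seed=seed,
    )
    gt, gt_params = b97_ground_truth()
    dataset = generate_dataset(spec, gt, gt_params)
    scale = dataset_scale(dataset)
    initial = _single_channel_empty(max_instructions=6)
    # p3 is the designated transform gamma; p0..p2 are free arguments
    mutation_config = MutationConfig(
        allowed_ops=("add", "mac", "power", "transform"),
        allowed_exponents=(2,),
        channels=("x",),
        gamma_pool=("p3",),
    )
    fit_config = FitConfig(n_restarts=10, sigma0=0.3, max_evals=2000,
                           stagnation_gens=20, seed=seed,
                           stop_when_below=1e-6 * scale)
    evolution_config = EvolutionConfig(
        population_size=100, tournament_size=10, budget=budget, seed=seed,
    )
    return DemoFixture(
        dataset=dataset, ground_truth=gt, ground_params=gt_params,
        initial=initial, mutation_config=mutation_config,
        fit_config=fit_config, evolution_config=evolution_config,
        scale=scale,
    )


def run_b97_rediscovery(seed: int, budget: int = 4000, **fixture_kw):
    """One from-scratch rediscovery run; returns (first_success_step, result).

    Success: an individual whose exchange program, at its fitted parameters,
    is algebraically a quadratic in one finite-domain transform of x2 (the
    published gradient-correction family) *and* whose validation error is
    below 1e-3 of the data scale.  ``first_success_step`` is None when the
    budget is exhausted without success.
    """
    from .equivalence import matches_b97_form
    from .evolution import run_evolution

    fx = b97_demo_fixture(seed=seed, budget=budget, **fixture_kw)
    threshold = 1e-3 * fx.scale

    def stop(ind, step):
        return ind.j_val < threshold and matches_b97_form(
            ind.functional.programs["x"], ind.params)

    result = run_evolution(fx.initial, fx.dataset, fx.mutation_config,
                           fx.fit_config, fx.evolution_config, stop=stop)
    return result.stopped_at, result


def _single_channel_empty(max_instructions: int = 6) -> SymbolicFunctional:
    """Empty functional whose exchange channel carries the demo workspace
    (x2; p0..p3; v0, v1, F) and whose correlation channels stay inert."""
    ws = (
        Symbol("x2", "feature"),
        Symbol("p0", "parameter"), Symbol("p1", "parameter"),
        Symbol("p2", "parameter"), Symbol("p3", "parameter"),
        Symbol("v0", "variable"), Symbol("v1", "variable"),
        Symbol("F", "variable"),
    )
    inert = (Symbol("x2", "feature"), Symbol("F", "variable"))
    return SymbolicFunctional({
        "x": InstructionProgram(workspace=ws, max_instructions=max_instructions),
        "css": InstructionProgram(workspace=inert),
        "cos": InstructionProgram(workspace=inert),
    })
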