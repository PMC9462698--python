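"""Energetic datasets, the weighted-RMSD objective, and multi-restart CMA-ES
parameter fitting for a fixed symbolic functional form.

A *data point* is a signed combination of system energies (e.g. an
isomerization energy is the difference of two total energies) with a
reference value in kcal/mol, a data-type label and a sample weight.  The
training / validation / test objective is the weighted root mean square
deviation

    J_S = sqrt( (1/N) * sum_{i in S} w_i * (E_i - E_i_ref)**2 )

in kcal/mol.  All scalar parameters of a functional form are treated as
nonlinear and optimized jointly by CMA-ES, restarted ``n_restarts`` times
from initial guesses drawn from a unit Gaussian, with every parameter
box-constrained to [-10, 10]; the restart with the lowest training error
wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cmaes import cmaes_minimize
from .functionals import (
    DEFAULT_LDA,
    HARTREE_TO_KCAL,
    GridSystem,
    LdaKernel,
    exc_semilocal,
    lda_energy_densities,
)
from .programs import CHANNELS, SymbolicFunctional, execute_program

__all__ = [
    "DataPoint",
    "EnergyDataset",
    "FitConfig",
    "FitResult",
    "DEFAULT_TYPE_WEIGHTS",
    "SPLITS",
    "wrmsd",
    "predict_datapoints",
    "fit_parameters",
    "evaluate_functional",
    "DatasetEvaluator",
    "used_parameters",
]

SPLITS = ("train", "validation", "test")

#: Default per-type sample weights for the emulated dataset structure.
DEFAULT_TYPE_WEIGHTS = {
    "TCD": 0.1,
    "TCE": 1.0,
    "AE18": 1.0,
    "NCD": 10.0,
    "ID": 10.0,
    "BH": 10.0,
    "NCE": 100.0,
    "IE": 100.0,
    "RG10": 10000.0,
}


@dataclass(frozen=True)
class DataPoint:
    """One energetic datum: a signed combination of system energies."""

    id: str
    terms: tuple[tuple[str, float], ...]
    reference: float          # kcal/mol
    data_type: str
    weight: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple((str(l), float(c)) for l, c in self.terms))
        if not self.terms:
            raise ValueError("data point needs at least one term")
        if not self.weight > 0:
            raise ValueError("sample weight must be positive")


@dataclass
class EnergyDataset:
    """Grid systems plus typed, weighted data points in three splits.

    ``offsets`` holds the fixed non-XC part of each system's total energy
    (kcal/mol), added to the semilocal XC energy when predicting.
    """

    systems: dict[str, GridSystem]
    splits: dict[str, list[DataPoint]]
    offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in SPLITS:
            self.splits.setdefault(name, [])
        ids = [dp.id for name in SPLITS for dp in self.splits[name]]
        if len(set(ids)) != len(ids):
            raise ValueError("data point ids must be unique across splits")
        for name in SPLITS:
            for dp in self.splits[name]:
                for label, _ in dp.terms:
                    if label not in self.systems:
                        raise ValueError(f"{dp.id}: unknown system {label!r}")
        for label in self.systems:
            self.offsets.setdefault(label, 0.0)

    def datapoints(self, split) -> list[DataPoint]:
        if isinstance(split, str):
            return self.splits[split]
        return list(split)

    # -- plain-text IO -----------------------------------------------------
    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for label, sys in self.systems.items():
            for r, g, t, q in zip(sys.rho, sys.x2, sys.w, sys.quad_weights):
                rows.append({"label": label, "rho": r, "x2": g, "w": t, "weight": q})
        pd.DataFrame(rows).to_csv(outdir / "systems.csv", index=False)
        dps = []
        manifest = {}
        for name in SPLITS:
            manifest[name] = [dp.id for dp in self.splits[name]]
            for dp in self.splits[name]:
                dps.append({
                    "id": dp.id,
                    "data_type": dp.data_type,
                    "weight": dp.weight,
                    "reference_kcalmol": dp.reference,
                    "terms": ";".join(f"{l}:{c:g}" for l, c in dp.terms),
                })
        pd.DataFrame(dps).to_csv(outdir / "datapoints.csv", index=False)
        (outdir / "splits.json").write_text(json.dumps(manifest, indent=1))
        (outdir / "offsets.json").write_text(json.dumps(self.offsets, indent=1))

    @classmethod
    def load(cls, outdir) -> "EnergyDataset":
        outdir = Path(outdir)
        sys_df = pd.read_csv(outdir / "systems.csv")
        systems = {
            str(label): GridSystem(
                label=str(label),
                rho=grp["rho"].to_numpy(),
                x2=grp["x2"].to_numpy(),
                w=grp["w"].to_numpy(),
                quad_weights=grp["weight"].to_numpy(),
            )
            for label, grp in sys_df.groupby("label", sort=False)
        }
        dp_df = pd.read_csv(outdir / "datapoints.csv")
        by_id = {}
        for row in dp_df.itertuples(index=False):
            terms = tuple(
                (part.split(":")[0], float(part.split(":")[1]))
                for part in row.terms.split(";")
            )
            by_id[row.id] = DataPoint(
                id=row.id, terms=terms, reference=row.reference_kcalmol,
                data_type=row.data_type, weight=row.weight,
            )
        manifest = json.loads((outdir / "splits.json").read_text())
        splits = {name: [by_id[i] for i in manifest.get(name, [])] for name in SPLITS}
        offsets = json.loads((outdir / "offsets.json").read_text())
        return cls(systems=systems, splits=splits, offsets=offsets)


@dataclass(frozen=True)
class FitConfig:
    """Settings of the multi-restart CMA-ES parameter fit."""

    n_restarts: int = 5
    sigma0: float = 0.3
    bounds: tuple[float, float] = (-10.0, 10.0)
    max_evals: int | None = None        # per restart; default 5000 * n_params
    popsize: int | None = None          # CMA-ES default 4 + floor(3 ln d)
    ftol_rel: float = 1e-12
    stagnation_gens: int = 30
    stop_when_below: float | None = None  # skip remaining restarts below this J
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be an increasing pair")


@dataclass
class FitResult:
    params: dict[str, float]
    j_train: float
    n_evals: int
    unfit: bool

    def as_tuple(self) -> tuple[dict[str, float], float]:
        return self.params, self.j_train


def wrmsd(predictions, split: Sequence[DataPoint]) -> float:
    """Weighted root mean square deviation of ``predictions`` from references."""
    split = list(split)
    if not split:
        raise ValueError("empty split")
    pred = np.asarray(predictions, dtype=float)
    if pred.shape[-1] != len(split):
        raise ValueError("predictions misaligned with split")
    ref = np.array([dp.reference for dp in split])
    w = np.array([dp.weight for dp in split])
    return float(np.sqrt(np.mean(w * (pred - ref) ** 2, axis=-1)))


def used_parameters(functional: SymbolicFunctional) -> tuple[str, ...]:
    """Parameters actually referenced by some instruction, in stable order.

    Parameters declared in a workspace but never read cannot influence the
    output and are excluded from the optimization.
    """
    referenced = set()
    for ch in CHANNELS:
        for ins in functional.programs[ch].instructions:
            referenced.update(ins.referenced())
    return tuple(p for p in functional.parameter_names if p in referenced)


def predict_datapoints(
    functional: SymbolicFunctional,
    params: Mapping[str, float],
    dataset: EnergyDataset,
    split="train",
    lda: LdaKernel = DEFAULT_LDA,
) -> np.ndarray:
    """Per-datapoint energies ``E_i = sum_terms coeff * (offset + E_xc)``
    in kcal/mol; an invalid functional evaluation yields ``nan``.

    Reference implementation over :func:`exc_semilocal`; the fitting loop
    uses the vectorized :class:`DatasetEvaluator` path instead.
    """
    dps = dataset.datapoints(split)
    labels = {l for dp in dps for l, _ in dp.terms}
    energies = {}
    for label in labels:
        e, ok = exc_semilocal(dataset.systems[label], functional, params, lda,
                              return_valid=True)
        energies[label] = dataset.offsets[label] + HARTREE_TO_KCAL * e if ok else np.nan
    return np.array([
        sum(c * energies[l] for l, c in dp.terms) for dp in dps
    ])


class DatasetEvaluator:
    """Vectorized predictor: one batched program execution per generation.

    Precomputes, once per dataset, the concatenated grid features, the
    LDA-energy-density-times-quadrature-weight vectors per channel, the
    per-system segment boundaries and the (systems x datapoints) signed
    coefficient matrices per split — so evaluating the WRMSD of ``k``
    parameter sets costs ``k``-row broadcasting only.
    """

    def __init__(self, dataset: EnergyDataset, lda: LdaKernel = DEFAULT_LDA):
        self.dataset = dataset
        self.labels = list(dataset.systems)
        index = {l: i for i, l in enumerate(self.labels)}
        systems = [dataset.systems[l] for l in self.labels]
        self.features = {
            name: np.concatenate([s.feature_values()[name] for s in systems])
            for name in ("rho", "x2", "x", "w")
        }
        self.seg = np.concatenate([[0], np.cumsum([len(s) for s in systems])])[:-1]
        e_x, e_ss, e_os = lda_energy_densities(self.features["rho"], lda)
        wq = np.concatenate([s.quad_weights for s in systems])
        self.wq_e = {"x": wq * e_x, "css": wq * e_ss, "cos": wq * e_os}
        self.offsets = np.array([dataset.offsets[l] for l in self.labels])
        self._split = {}
        for name in SPLITS:
            dps = dataset.splits[name]
            T = np.zeros((len(self.labels), len(dps)))
            for j, dp in enumerate(dps):
                for l, c in dp.terms:
                    T[index[l], j] += c
            ref = np.array([dp.reference for dp in dps])
            w = np.array([dp.weight for dp in dps])
            off = self.offsets @ T
            self._split[name] = (T, ref, w, off)

    # -- core batched path -------------------------------------------------
    def system_energies(self, functional, params) -> tuple[np.ndarray, np.ndarray]:
        """(k, n_systems) XC energies in hartree and (k,) validity flags.

        ``params`` maps names to scalars or (k, 1) columns.
        """
        total = None
        valid = True
        for ch in CHANNELS:
            prog = functional.programs[ch]
            if not prog.instructions:
                continue
            F, v = execute_program(prog, self.features, params, return_valid=True)
            contrib = np.add.reduceat(self.wq_e[ch] * F, self.seg, axis=-1)
            total = contrib if total is None else total + contrib
            valid = np.logical_and(valid, v)
        if total is None:
            total = np.zeros(len(self.labels))
        return total, np.broadcast_to(valid, total.shape[:-1])

    def split_wrmsd(self, functional, params, split: str) -> np.ndarray:
        """WRMSD per batch row (``inf`` for invalid rows)."""
        T, ref, w, off = self._split[split]
        e_sys, valid = self.system_energies(functional, params)
        E = HARTREE_TO_KCAL * e_sys @ T + off
        with np.errstate(invalid="ignore", over="ignore"):
            j = np.sqrt(np.mean(w * (E - ref) ** 2, axis=-1))
        j = np.where(np.isfinite(j) & valid, j, np.inf)
        return j

    def evaluate(self, functional, params: Mapping[str, float]) -> dict[str, float]:
        """J_train / J_validation / J_test at one parameter assignment."""
        return {
            name: float(self.split_wrmsd(functional, params, name))
            for name in SPLITS
        }

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        functional: SymbolicFunctional,
        config: FitConfig,
        rng: np.random.Generator | None = None,
    ) -> FitResult:
        """Multi-restart CMA-ES minimization of the training WRMSD."""
        if rng is None:
            rng = np.random.default_rng(config.seed)
        names = used_parameters(functional)
        d = len(names)
        base = {p: 0.0 for p in functional.parameter_names}
        if d == 0:
            j = float(self.split_wrmsd(functional, base, "train"))
            return FitResult(params=base, j_train=j, n_evals=1,
                             unfit=not np.isfinite(j))

        def objective(X: np.ndarray) -> np.ndarray:
            params = dict(base)
            params.update({n: X[:, i:i + 1] for i, n in enumerate(names)})
            return self.split_wrmsd(functional, params, "train")

        best_x, best_j, n_evals = None, np.inf, 0
        max_evals = config.max_evals if config.max_evals is not None else 5000 * d
        for _ in range(config.n_restarts):
            x0 = rng.standard_normal(d)
            res = cmaes_minimize(
                objective, x0, config.sigma0, rng, bounds=config.bounds,
                max_evals=max_evals, popsize=config.popsize,
                ftol_rel=config.ftol_rel, stagnation_gens=config.stagnation_gens,
                target_f=config.stop_when_below,
            )
            n_evals += res.n_evals
            if res.fun < best_j:
                best_j, best_x = res.fun, res.x
            if config.stop_when_below is not None and best_j <= config.stop_when_below:
                break
        params = dict(base)
        if best_x is not None and np.isfinite(best_j):
            params.update(dict(zip(names, best_x.tolist())))
            return FitResult(params=params, j_train=float(best_j),
                             n_evals=n_evals, unfit=False)
        return FitResult(params=params, j_train=float("inf"),
                         n_evals=n_evals, unfit=True)


def fit_parameters(
    functional: SymbolicFunctional,
    dataset: EnergyDataset,
    config: FitConfig = FitConfig(),
    rng: np.random.Generator | None = None,
    lda: LdaKernel = DEFAULT_LDA,
) -> FitResult:
    """Fit the free scalars of ``functional`` to the training split.

    Zero-parameter forms skip the optimizer; otherwise ``n_restarts``
    independent CMA-ES runs (initial mean ~ N(0, I), box [-10, 10]) are
    performed and the lowest training error wins.  Deterministic given
    ``rng`` (or ``config.seed``).
    """
    return DatasetEvaluator(dataset, lda).fit(functional, config, rng)


def evaluate_functional(
    functional: SymbolicFunctional,
    params: Mapping[str, float],
    dataset: EnergyDataset,
    lda: LdaKernel = DEFAULT_LDA,
) -> dict[str, float]:
    """WRMSD on all three splits at a fixed parameter assignment."""
    return DatasetEvaluator(dataset, lda).evaluate(functional, params)
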