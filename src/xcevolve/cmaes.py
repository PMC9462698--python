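"""Covariance matrix adaptation evolution strategy (CMA-ES) for bounded,
derivative-free minimization of the training objective.

A compact implementation of the standard (mu/mu_w, lambda) update equations
(rank-one + rank-mu covariance update, cumulative step-size adaptation).
It is written for the low-dimensional (d <= ~20) parameter-fitting problems
that arise when training a symbolic functional: the objective is evaluated
*batched* — ``f(X)`` receives the whole population as an ``(n, d)`` array
and returns ``(n,)`` values — which keeps the per-generation Python
overhead negligible next to the vectorized grid evaluation.

Box constraints are handled by repair-plus-penalty: candidates are clipped
into the box, the objective is evaluated at the repaired (feasible) point,
and a quadratic penalty on the repair distance steers the distribution back
inside.  The reported best is always a feasible point with its raw
objective value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["CmaResult", "cmaes_minimize"]

#: Weight of the quadratic out-of-box repair penalty.
_BOUND_PENALTY = 100.0


@dataclass
class CmaResult:
    x: np.ndarray
    fun: float
    n_evals: int
    n_generations: int
    stop_reason: str


def cmaes_minimize(
    f: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    sigma0: float,
    rng: np.random.Generator,
    bounds: tuple[float, float] = (-10.0, 10.0),
    max_evals: int | None = None,
    popsize: int | None = None,
    ftol_rel: float = 1e-12,
    stagnation_gens: int = 30,
    target_f: float | None = None,
) -> CmaResult:
    """Minimize ``f`` starting from mean ``x0`` with step size ``sigma0``.

    Stops on the evaluation budget (default ``5000 * d``), on step-size or
    covariance degeneracy, when the best value has not improved relatively
    by ``ftol_rel`` over ``stagnation_gens`` generations, or when
    ``target_f`` is reached.
    """
    x0 = np.asarray(x0, dtype=float)
    d = len(x0)
    if d == 0:
        raise ValueError("zero-dimensional problem")
    lo, hi = bounds
    lam = popsize if popsize is not None else 4 + int(3 * np.log(d))
    lam = max(lam, 4)
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / d) / (d + 4 + 2 * mueff / d)
    cs = (mueff + 2) / (d + mueff + 5)
    c1 = 2 / ((d + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((d + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (d + 1)) - 1) + cs
    chi_n = np.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d * d))

    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(d)
    ps = np.zeros(d)
    pc = np.zeros(d)

    if max_evals is None:
        max_evals = 5000 * d

    best_x = np.clip(mean, lo, hi)
    best_f = float(f(best_x[None, :])[0])
    n_evals = 1
    gen = 0
    history: list[float] = [best_f]
    reason = "max_evals"

    while n_evals < max_evals:
        gen += 1
        try:
            evals, B = np.linalg.eigh(C)
        except np.linalg.LinAlgError:
            reason = "covariance_degenerate"
            break
        evals = np.maximum(evals, 0.0)
        if evals.max() <= 0 or evals.max() / max(evals.min(), 1e-300) > 1e14:
            reason = "ill_conditioned"
            break
        D = np.sqrt(evals)

        Z = rng.standard_normal((lam, d))
        Y = Z * D @ B.T                       # y_k = B D z_k
        X = mean + sigma * Y
        Xr = np.clip(X, lo, hi)
        f_raw = np.asarray(f(Xr), dtype=float)
        penalty = _BOUND_PENALTY * np.sum((X - Xr) ** 2, axis=1)
        f_raw = np.where(np.isfinite(f_raw), f_raw, np.inf)
        f_sel = f_raw + penalty
        n_evals += lam

        i_best = int(np.argmin(f_raw))
        if f_raw[i_best] < best_f:
            best_f = float(f_raw[i_best])
            best_x = Xr[i_best].copy()

        order = np.argsort(f_sel, kind="stable")[:mu]
        y_w = w @ Y[order]
        mean = mean + sigma * y_w

        # cumulative step-size adaptation uses C^{-1/2} y_w
        inv_sqrt_y = B @ ((B.T @ y_w) / np.maximum(D, 1e-300))
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * inv_sqrt_y
        hsig = float(
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * gen)) / chi_n
            < 1.4 + 2 / (d + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w

        rank_mu = (Y[order] * w[:, None]).T @ Y[order]
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        sigma *= float(np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1)))

        if target_f is not None and best_f <= target_f:
            reason = "target_reached"
            break
        if not np.isfinite(sigma) or sigma < 1e-14 or sigma > 1e8:
            reason = "sigma_degenerate"
            break
        history.append(best_f)
        if len(history) > stagnation_gens:
            old = history[-stagnation_gens - 1]
            if old - best_f <= ftol_rel * (abs(old) + 1e-30):
                reason = "stagnation"
                break

    return CmaResult(x=best_x, fun=best_f, n_evals=n_evals, n_generations=gen,
                     stop_reason=reason)
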