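"""Detection of equivalent functional forms.

A mutated program often differs from an already-trained one only by dead
instructions or by a renaming of intermediates; training it again would
waste the bulk of the search budget.  Forms are therefore reduced to a
*fingerprint*: the program is canonicalized by dead-code elimination (only
the backward dependency slice of the result variable ``F`` survives) and
then evaluated on a fixed pseudo-random probe set of feature points under
several random parameter assignments; the quantized outputs are hashed.
Equal digests mean the two programs compute the same function of features
*and* parameters jointly on the probe set, so a cached fit can be reused.

Equivalence under re-parameterization (two families whose members coincide
only after a nonlinear change of parameters) is deliberately not detected:
such forms are trained independently.  A lightweight numeric test for
membership of the quadratic gradient-correction family
``c0 + c1*u + c2*u**2`` is provided for analyzing rediscovery runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .programs import (
    CHANNELS,
    RESULT_VARIABLE,
    InstructionProgram,
    SymbolicFunctional,
    execute_program,
)

__all__ = [
    "ProbeSpec",
    "Fingerprint",
    "CacheRecord",
    "EquivalenceCache",
    "canonicalize",
    "canonicalize_functional",
    "fingerprint",
    "functional_fingerprint",
    "seen_before",
    "matches_b97_form",
]


def canonicalize(program: InstructionProgram) -> InstructionProgram:
    """Remove instructions outside the backward dependency slice of ``F``.

    Idempotent; the surviving program renders to an expression numerically
    identical to the input's.
    """
    live = {RESULT_VARIABLE}
    keep = []
    for ins in reversed(program.instructions):
        if ins.output not in live:
            continue
        keep.append(ins)
        if ins.op != "mac":          # mac implicitly reads its own output
            live.discard(ins.output)
        live.update(ins.inputs)
        if ins.gamma is not None:
            live.add(ins.gamma)
    return program.with_instructions(reversed(keep))


def canonicalize_functional(functional: SymbolicFunctional) -> SymbolicFunctional:
    return SymbolicFunctional(
        {ch: canonicalize(functional.programs[ch]) for ch in CHANNELS}
    )


@dataclass(frozen=True)
class ProbeSpec:
    """Deterministic probe-set definition shared by all fingerprints."""

    n_probe_points: int = 64
    n_parameter_draws: int = 4
    quantization_decimals: int = 8
    probe_seed: int = 20220909


#: Feature-wise probe distributions over realistic ranges.
def _probe_feature(name: str, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng([seed, abs(hash_name(name))])
    if name in ("x2",):
        return 10.0 ** rng.uniform(-4, 4, n)
    if name in ("x", "rho"):
        return 10.0 ** rng.uniform(-2, 2, n)
    if name == "w":
        return rng.uniform(-1.0, 1.0, n)
    if name == "u":
        return rng.uniform(0.0, 1.0, n)
    return rng.standard_normal(n)


def hash_name(name: str) -> int:
    """Stable (process-independent) integer hash of a symbol name."""
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")


@dataclass(frozen=True)
class Fingerprint:
    digest: str
    probe_spec: ProbeSpec
    param_order: tuple[str, ...]


def _first_use_parameter_order(program: InstructionProgram) -> tuple[str, ...]:
    kind_of = program.kind_of
    order: dict[str, None] = {}
    for ins in program.instructions:
        for name in ins.inputs + ((ins.gamma,) if ins.gamma else ()):
            if kind_of.get(name) == "parameter":
                order.setdefault(name)
    return tuple(order)


_NAN, _PINF, _NINF = 1.2345678e300, 2.2e300, -2.2e300


def _probe_matrix(program: InstructionProgram, spec: ProbeSpec) -> np.ndarray:
    """(n_parameter_draws, n_probe_points) quantized probe outputs."""
    canon = canonicalize(program)
    kind_of = canon.kind_of
    feats = sorted({
        n for ins in canon.instructions for n in ins.inputs
        if kind_of.get(n) == "feature"
    })
    order = _first_use_parameter_order(canon)
    features = {f: _probe_feature(f, spec.n_probe_points, spec.probe_seed)
                for f in feats}
    # declared-but-unused features still need values for the executor contract
    for f in canon.names("feature"):
        features.setdefault(f, np.zeros(spec.n_probe_points))
    prng = np.random.default_rng([spec.probe_seed, len(order), 7])
    draws = np.clip(prng.standard_normal((spec.n_parameter_draws, len(order))),
                    -10.0, 10.0)
    params: dict[str, object] = {n: draws[:, i:i + 1] for i, n in enumerate(order)}
    for p in canon.names("parameter"):   # declared-but-unused parameters
        params.setdefault(p, 0.0)
    out = execute_program(canon, features, params)
    out = np.atleast_2d(np.asarray(out, dtype=float))
    q = np.round(out, spec.quantization_decimals) + 0.0   # normalize -0.0
    q = np.where(np.isnan(q), _NAN, q)
    q = np.where(np.isposinf(q), _PINF, q)
    q = np.where(np.isneginf(q), _NINF, q)
    return q


def fingerprint(program: InstructionProgram, spec: ProbeSpec = ProbeSpec()) -> Fingerprint:
    """Canonicalize, probe, quantize, hash."""
    canon = canonicalize(program)
    order = _first_use_parameter_order(canon)
    q = _probe_matrix(program, spec)
    h = hashlib.sha256()
    h.update(json.dumps({
        "spec": [spec.n_probe_points, spec.n_parameter_draws,
                 spec.quantization_decimals, spec.probe_seed],
        "n_params": len(order),
    }).encode())
    h.update(np.ascontiguousarray(q).tobytes())
    return Fingerprint(digest=h.hexdigest(), probe_spec=spec, param_order=order)


def functional_fingerprint(
    functional: SymbolicFunctional, spec: ProbeSpec = ProbeSpec()
) -> Fingerprint:
    """Joint fingerprint of the three channels, with a stable parameter order."""
    fps = [fingerprint(functional.programs[ch], spec) for ch in CHANNELS]
    h = hashlib.sha256("|".join(fp.digest for fp in fps).encode())
    order: dict[str, None] = {}
    for fp in fps:
        for name in fp.param_order:
            order.setdefault(name)
    return Fingerprint(digest=h.hexdigest(), probe_spec=spec,
                       param_order=tuple(order))


@dataclass
class CacheRecord:
    param_values: tuple[float, ...]    # aligned with the fingerprint's param_order
    j_train: float
    j_val: float
    expression: str

    def params_for(self, fp: Fingerprint) -> dict[str, float]:
        return dict(zip(fp.param_order, self.param_values))


class EquivalenceCache:
    """digest -> fitted result, persisted as JSON lines for warm restarts."""

    def __init__(self) -> None:
        self._records: dict[str, CacheRecord] = {}

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, digest: str) -> bool:
        return digest in self._records

    def lookup(self, digest: str) -> CacheRecord | None:
        return self._records.get(digest)

    def insert(self, digest: str, record: CacheRecord) -> None:
        self._records[digest] = record

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for digest, r in self._records.items():
                fh.write(json.dumps({
                    "digest": digest, "params": list(r.param_values),
                    "J_train": r.j_train, "J_val": r.j_val,
                    "expression": r.expression,
                }) + "\n")

    @classmethod
    def load(cls, path) -> "EquivalenceCache":
        cache = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            cache.insert(d["digest"], CacheRecord(
                param_values=tuple(d["params"]), j_train=d["J_train"],
                j_val=d["J_val"], expression=d["expression"],
            ))
        return cache


def seen_before(cache: EquivalenceCache, fp: Fingerprint):
    """Membership check returning ``(hit, cached record or None)``."""
    record = cache.lookup(fp.digest)
    return record is not None, record


def matches_b97_form(
    program: InstructionProgram,
    params: Mapping[str, float],
    tol: float = 1e-8,
    require_quadratic: bool = False,
) -> bool:
    """Is the program, at the given parameter values, a member of the family
    ``c0 + c1*u + c2*u**2`` with ``u = g*x2/(1+g*x2)`` for some (c, g)?

    Checked as an algebraic identity through a dense probe: the program and
    the candidate quadratic (least-squares in ``u`` for each gamma bound to
    a transform in the canonical slice) are rational functions of ``x2``,
    so agreement to ~machine precision on hundreds of probe points implies
    identity.  ``require_quadratic`` additionally demands genuinely nonzero
    c1 and c2 (the non-degenerate published form).
    """
    canon = canonicalize(program)
    feats = {n for ins in canon.instructions for n in ins.inputs
             if canon.kind_of.get(n) == "feature"}
    if feats - {"x2"}:
        return False
    x2 = np.geomspace(1e-4, 1e4, 257)
    full = {p: 0.0 for p in canon.names("parameter")}
    full.update({k: float(v) for k, v in params.items()})
    params = full
    try:
        fvals, valid = execute_program(canon, {"x2": x2}, params, return_valid=True)
    except ValueError:
        return False
    if not valid:
        return False
    scale = max(1.0, float(np.max(np.abs(fvals))))
    gammas = {params[ins.gamma] for ins in canon.instructions
              if ins.gamma is not None}
    if not gammas:
        # constant in x2: degenerate member with c1 = c2 = 0
        const = np.ptp(fvals) <= tol * scale
        return bool(const and not require_quadratic)
    for g in gammas:
        if g == 0 or not np.isfinite(g):
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            u = g * x2 / (1.0 + g * x2)
        if not np.all(np.isfinite(u)):   # pole inside the probe range
            continue
        A = np.stack([np.ones_like(u), u, u * u], axis=1)
        try:
            coef, *_ = np.linalg.lstsq(A, fvals, rcond=None)
        except np.linalg.LinAlgError:
            continue
        if np.max(np.abs(A @ coef - fvals)) <= tol * scale:
            if require_quadratic and (abs(coef[1]) < 1e-6 or abs(coef[2]) < 1e-6):
                continue
            return True
    return False
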