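"""Feature transforms, LDA energy-density kernels, published enhancement
factors (B97, its rediscovered equivalent, wB97M-V, GAS22) and semilocal
exchange-correlation energy assembly.

Conventions
-----------
Atomic units for densities and grids; energies from :func:`exc_semilocal`
are in hartree.  The dimensionless features are

* ``x``  — reduced density gradient ``x = 2**(1/3) * |grad rho| / rho**(4/3)``
* ``x2`` — its square (the feature most search spaces expose)
* ``u``  — finite-domain transform ``u = g*x2 / (1 + g*x2)`` in [0, 1)
* ``w``  — bounded kinetic-energy-density feature in [-1, 1]
* ``s``  — conventional rescaling ``s = x / (2 * (3*pi**2)**(1/3))``
* ``rs`` — Wigner-Seitz radius ``rs = (3/(4*pi*rho))**(1/3)``

The LDA correlation split into same-spin and opposite-spin channels is a
pluggable kernel; the default ships a deliberately simple analytic
surrogate (rho**(4/3)-scaled, *not* a physical parameterization) that is
sufficient for exercising the search and fitting machinery on synthetic
data.  The exchange kernel defaults to full-range LDA exchange.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np

from .programs import (
    CHANNELS,
    Instruction,
    InstructionProgram,
    Symbol,
    SymbolicFunctional,
    execute_program,
)

__all__ = [
    "HARTREE_TO_KCAL",
    "FeatureSet",
    "GridSystem",
    "LdaKernel",
    "DEFAULT_LDA",
    "compute_features",
    "b97_enhancement",
    "eq5_enhancement",
    "expand_to_b97",
    "wb97mv_enhancement",
    "gas22_enhancement",
    "lda_energy_densities",
    "exc_semilocal",
    "combined_fxc",
    "b97_program",
    "B97_PARAMS",
    "eq5_program",
    "EQ5_PARAMS",
    "power_series_program",
    "wb97mv_x_program",
    "wb97mv_functional",
    "gas22_functional",
    "load_gas22_coefficients",
    "load_wb97mv_coefficients",
    "WB97MV_TERM_SUBSETS",
]

HARTREE_TO_KCAL = 627.509474

#: Prefactor of full-range LDA exchange: e_x = -C_X * rho**(4/3).
_C_X = 0.75 * (3.0 / np.pi) ** (1.0 / 3.0)


def _load_data(name: str) -> dict:
    with resources.files("xcevolve.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_gas22_coefficients() -> dict:
    """Versioned GAS22 coefficient table shipped with the package."""
    return _load_data("gas22.json")


def load_wb97mv_coefficients() -> dict:
    """Versioned wB97M-V coefficient table shipped with the package."""
    return _load_data("wb97mv.json")


_GAS22 = load_gas22_coefficients()
_WB97MV = load_wb97mv_coefficients()

#: Admissible power-series term keys ('ij' multiplies w**i * u**j) per channel.
WB97MV_TERM_SUBSETS = {k: tuple(v) for k, v in _WB97MV["term_subsets"].items()}


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSet:
    """Per-point density features; arrays share one grid shape."""

    rho: np.ndarray
    x2: np.ndarray
    x: np.ndarray
    s: np.ndarray
    rs: np.ndarray
    w: np.ndarray | None = None
    u: np.ndarray | None = None

    def as_dict(self) -> dict[str, np.ndarray]:
        d = {"rho": self.rho, "x2": self.x2, "x": self.x, "s": self.s, "rs": self.rs}
        if self.w is not None:
            d["w"] = self.w
        if self.u is not None:
            d["u"] = self.u
        return d


def compute_features(
    rho,
    grad_norm=None,
    x2=None,
    w=None,
    gamma: float | None = None,
) -> FeatureSet:
    """Derive the dimensionless feature set from density-level quantities.

    Exactly one of ``grad_norm`` (|grad rho|) or ``x2`` must be supplied.
    ``w`` is accepted directly as a bounded input feature in [-1, 1] (the
    kinetic-energy-density map onto it lives upstream of this package).
    ``gamma`` additionally populates ``u = gamma*x2/(1+gamma*x2)``.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    if (grad_norm is None) == (x2 is None):
        raise ValueError("supply exactly one of grad_norm or x2")
    if x2 is None:
        grad_norm = np.asarray(grad_norm, dtype=float)
        x = 2.0 ** (1.0 / 3.0) * grad_norm / rho ** (4.0 / 3.0)
        x2 = x * x
    else:
        x2 = np.asarray(x2, dtype=float)
        if np.any(x2 < 0):
            raise ValueError("x2 must be nonnegative")
        x = np.sqrt(x2)
    s = x / (2.0 * (3.0 * np.pi**2) ** (1.0 / 3.0))
    rs = (3.0 / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
    u = None
    if gamma is not None:
        u = gamma * x2 / (1.0 + gamma * x2)
    if w is not None:
        w = np.asarray(w, dtype=float)
    return FeatureSet(rho=rho, x2=x2, x=x, s=s, rs=rs, w=w, u=u)


# ---------------------------------------------------------------------------
# Grid systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSystem:
    """Quadrature grid of one 'molecule': per-point features plus weights."""

    label: str
    rho: np.ndarray
    x2: np.ndarray
    w: np.ndarray
    quad_weights: np.ndarray

    def __post_init__(self) -> None:
        for name in ("rho", "x2", "w", "quad_weights"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = len(self.rho)
        if not (len(self.x2) == len(self.w) == len(self.quad_weights) == n):
            raise ValueError("grid arrays must have equal length")
        if np.any(self.quad_weights < 0):
            raise ValueError("quadrature weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.rho)

    def feature_values(self) -> dict[str, np.ndarray]:
        return {"rho": self.rho, "x2": self.x2, "x": np.sqrt(self.x2), "w": self.w}

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "points": [
                {"rho": r, "x2": g, "w": t, "weight": q}
                for r, g, t, q in zip(self.rho, self.x2, self.w, self.quad_weights)
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSystem":
        pts = d["points"]
        return cls(
            label=d["label"],
            rho=[p["rho"] for p in pts],
            x2=[p["x2"] for p in pts],
            w=[p["w"] for p in pts],
            quad_weights=[p["weight"] for p in pts],
        )


# ---------------------------------------------------------------------------
# LDA energy densities (pluggable)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdaKernel:
    """Pluggable LDA energy-density provider.

    Exchange is full-range LDA, ``e_x = -(3/4)(3/pi)**(1/3) * rho**(4/3)``.
    The same-/opposite-spin correlation split is a synthetic analytic
    surrogate ``e_c = -c * rho**(4/3)`` — not a physical correlation
    parameterization, but positive-definite in magnitude and smooth, which
    is all the search and fitting machinery requires of it.
    """

    c_ss: float = 0.04
    c_os: float = 0.08

    def __call__(self, rho) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rho = np.asarray(rho, dtype=float)
        if np.any(rho <= 0):
            raise ValueError("rho must be positive")
        r43 = rho ** (4.0 / 3.0)
        return -_C_X * r43, -self.c_ss * r43, -self.c_os * r43


DEFAULT_LDA = LdaKernel()


def lda_energy_densities(rho, kernel: LdaKernel | Callable = DEFAULT_LDA):
    """Per-point (e_x, e_c_ss, e_c_os) from the chosen LDA kernel."""
    return kernel(rho)


# ---------------------------------------------------------------------------
# Published enhancement factors (closed forms)
# ---------------------------------------------------------------------------

def b97_enhancement(x2, c0, c1, c2, gamma):
    """Quadratic gradient-correction form ``c0 + c1*u + c2*u**2``."""
    x2 = np.asarray(x2, dtype=float)
    u = gamma * x2 / (1.0 + gamma * x2)
    return c0 + c1 * u + c2 * u * u


def eq5_enhancement(x2, c0, c1, c2, gamma):
    """Rediscovered equivalent of the B97 form: ``c0**2 + c1*(c2 + u)**2``."""
    x2 = np.asarray(x2, dtype=float)
    u = gamma * x2 / (1.0 + gamma * x2)
    return c0 * c0 + c1 * (c2 + u) ** 2


def expand_to_b97(c0, c1, c2) -> tuple[float, float, float]:
    """Algebraic expansion of ``c0**2 + c1*(c2+u)**2`` into B97 coefficients.

    Returns ``(b0, b1, b2)`` with ``b0 = c0**2 + c1*c2**2``, ``b1 = 2*c1*c2``
    and ``b2 = c1``, so that the two forms agree identically in ``u``.
    """
    return c0 * c0 + c1 * c2 * c2, 2.0 * c1 * c2, c1


def wb97mv_enhancement(kind: str, u, w, coefficients: Mapping[str, float]):
    """Power series ``sum_ij c_ij * w**i * u**j`` over the channel's term subset.

    ``kind`` is one of ``x``, ``css``, ``cos``; supplying a coefficient key
    outside the channel's published subset is an error.
    """
    if kind not in WB97MV_TERM_SUBSETS:
        raise ValueError(f"unknown channel {kind!r}")
    allowed = set(WB97MV_TERM_SUBSETS[kind])
    extra = set(coefficients) - allowed
    if extra:
        raise ValueError(f"terms {sorted(extra)} not in the {kind} subset")
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    out = np.zeros(np.broadcast_shapes(u.shape, w.shape))
    for key, c in coefficients.items():
        i, j = int(key[0]), int(key[1])
        out = out + c * w**i * u**j
    return out


def gas22_enhancement(kind: str, x2=None, x=None, u=None, w=None,
                      x_exponent: Fraction | None = None):
    """GAS22 closed forms, evaluated exactly as published.

    The exchange and same-spin channels use channel-specific gammas for
    ``u`` (supplied ``u`` overrides the internal transform).  The
    opposite-spin channel carries an ``x**(3/2)`` term by default; the
    exponent is configurable through ``x_exponent`` because the power-series
    space the search explores treats it as a discrete choice.
    """
    tab = _GAS22[kind if kind in ("x", "css", "cos") else ""]
    if w is None:
        raise ValueError("w is required")
    w = np.asarray(w, dtype=float)
    if kind in ("x", "css"):
        if u is None:
            if x2 is None:
                if x is None:
                    raise ValueError("supply x2, x or u")
                x2 = np.asarray(x, float) ** 2
            g = tab["gamma"]
            x2 = np.asarray(x2, dtype=float)
            u = g * x2 / (1.0 + g * x2)
        u = np.asarray(u, dtype=float)
    if kind == "x":
        return tab["c0"] + tab["c_u"] * u + tab["c_w"] * w
    if kind == "css":
        u6 = u**6
        return (
            tab["c_u"] * u
            + tab["c_w"] * w
            + tab["c_w2"] * w**2
            + tab["c_u6"] * u6
            + tab["c_w4u6"] * w**4 * u6
        )
    if kind == "cos":
        if x is None:
            if x2 is None:
                raise ValueError("supply x or x2")
            x = np.sqrt(np.asarray(x2, dtype=float))
        x = np.asarray(x, dtype=float)
        e = Fraction(x_exponent) if x_exponent is not None else Fraction(tab["x_exponent"])
        xe = x ** float(e)
        w2 = w**2
        w6 = w**6
        return (
            tab["c0"]
            + tab["c_w2"] * w2
            + tab["c_w6"] * w6
            + tab["c_w6x"] * w6 * xe
            + tab["c_w2x"] * w2 * xe
        )
    raise ValueError(f"unknown channel {kind!r}")


# ---------------------------------------------------------------------------
# Semilocal energy assembly
# ---------------------------------------------------------------------------

def _channel_factors(functional, params, features, return_valid):
    out = {}
    valid = True
    for ch in CHANNELS:
        prog = functional.programs[ch]
        if prog.instructions:
            f, v = execute_program(prog, features, params, return_valid=True)
            valid = valid and bool(np.all(v))
        else:
            f = np.zeros(np.broadcast_shapes(*[np.shape(a) for a in features.values()]))
        out[ch] = f
    return (out, valid) if return_valid else out


def exc_semilocal(
    system: GridSystem,
    functional: SymbolicFunctional,
    params: Mapping[str, float],
    lda: LdaKernel | Callable = DEFAULT_LDA,
    return_valid: bool = False,
):
    """Semilocal XC energy of one system by quadrature, in hartree.

    ``sum_points quad_weight * (e_x*F_x + e_css*F_css + e_cos*F_cos)``.
    An invalid program evaluation (non-finite intermediate on the grid)
    yields ``nan`` (and ``valid=False`` when ``return_valid``).
    """
    feats = system.feature_values()
    factors, valid = _channel_factors(functional, params, feats, return_valid=True)
    e_x, e_ss, e_os = lda_energy_densities(system.rho, lda)
    dens = e_x * factors["x"] + e_ss * factors["css"] + e_os * factors["cos"]
    energy = float(np.dot(system.quad_weights, dens)) if valid else float("nan")
    if not np.isfinite(energy):
        energy, valid = float("nan"), False
    return (energy, valid) if return_valid else energy


def combined_fxc(
    features: FeatureSet | Mapping[str, np.ndarray],
    functional: SymbolicFunctional,
    params: Mapping[str, float],
    lda: LdaKernel | Callable = DEFAULT_LDA,
) -> np.ndarray:
    """Pointwise total enhancement over LDA.

    ``F_xc = (e_x*F_x + e_css*F_css + e_cos*F_cos) / (e_x + e_css + e_cos)``
    — the deviation of the XC energy density from its LDA value, the
    quantity conventionally plotted against ``s`` at fixed ``rs`` and ``w``.
    Points with a vanishing denominator (or an invalid program evaluation)
    come back non-finite rather than raising.
    """
    feats = features.as_dict() if isinstance(features, FeatureSet) else dict(features)
    factors = _channel_factors(functional, params, feats, return_valid=False)
    e_x, e_ss, e_os = lda_energy_densities(feats["rho"], lda)
    num = e_x * factors["x"] + e_ss * factors["css"] + e_os * factors["cos"]
    den = e_x + e_ss + e_os
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


# ---------------------------------------------------------------------------
# Instruction-program encodings of the published forms
# ---------------------------------------------------------------------------

#: Published B97 exchange coefficients (gradient-correction fit).
B97_PARAMS = {"c0": 0.8094, "c1": 0.5073, "c2": 0.7481, "gam": 0.004}

#: Parameters of the rediscovered, algebraically equivalent form.
EQ5_PARAMS = {"c0": 0.8504, "c1": 0.7480, "c2": 0.3394, "gam": 0.0040}


def _ws(features, params, variables):
    ws = [Symbol(f, "feature") for f in features]
    ws += [Symbol(p, "parameter") for p in params]
    ws += [Symbol(v, "variable") for v in variables]
    ws.append(Symbol("F", "variable"))
    return tuple(ws)


def b97_program() -> InstructionProgram:
    """Five-instruction encoding of ``c0 + c1*u + c2*u**2`` over feature x2."""
    return InstructionProgram(
        workspace=_ws(("x2",), ("c0", "c1", "c2", "gam"), ("v0", "v1")),
        instructions=(
            Instruction("transform", "v0", ("x2",), gamma="gam"),
            Instruction("mac", "F", ("c1", "v0")),
            Instruction("power", "v1", ("v0",), exponent=Fraction(2)),
            Instruction("mac", "F", ("c2", "v1")),
            Instruction("add", "F", ("F", "c0")),
        ),
        max_instructions=6,
    )


def eq5_program() -> InstructionProgram:
    """Six-instruction encoding of ``c0**2 + c1*(c2 + u)**2``."""
    return InstructionProgram(
        workspace=_ws(("x2",), ("c0", "c1", "c2", "gam"), ("v0", "v1")),
        instructions=(
            Instruction("transform", "v0", ("x2",), gamma="gam"),
            Instruction("add", "v0", ("c2", "v0")),
            Instruction("power", "v0", ("v0",), exponent=Fraction(2)),
            Instruction("mac", "F", ("c1", "v0")),
            Instruction("power", "v1", ("c0",), exponent=Fraction(2)),
            Instruction("add", "F", ("F", "v1")),
        ),
        max_instructions=6,
    )


def power_series_program(
    terms: Sequence[str],
    prefix: str = "",
    u_feature: bool = False,
) -> InstructionProgram:
    """Encode the power series ``sum_ij c_ij * w**i * u**j`` as instructions.

    ``terms`` lists 'ij' keys.  With ``u_feature=True`` the program reads
    ``u`` directly as a feature (no transform instruction); otherwise it
    derives ``u`` from ``x2`` through a finite-domain transform whose gamma
    is the bound parameter ``{prefix}g``.  Coefficient parameters are named
    ``{prefix}c{ij}``.
    """
    features = ("u", "w") if u_feature else ("x2", "w")
    params = [f"{prefix}c{t}" for t in terms]
    if not u_feature:
        params.append(f"{prefix}g")
    ins: list[Instruction] = []
    u_sym = "u"
    if not u_feature:
        ins.append(Instruction("transform", "vu", ("x2",), gamma=f"{prefix}g"))
        u_sym = "vu"

    def monomial(sym: str, n: int, into: str) -> str:
        """Return a symbol holding sym**n, emitting instructions as needed."""
        if n == 1:
            return sym
        if n in (2, 3, 4, 6):
            ins.append(Instruction("power", into, (sym,), exponent=Fraction(n)))
            return into
        raise ValueError(f"unsupported monomial order {n}")

    for t in terms:
        i, j = int(t[0]), int(t[1])
        c = f"{prefix}c{t}"
        if i == 0 and j == 0:
            ins.append(Instruction("add", "F", ("F", c)))
            continue
        if i == 0:
            factor = monomial(u_sym, j, "va")
        elif j == 0:
            factor = monomial("w", i, "va")
        else:
            fw = monomial("w", i, "va")
            fu = monomial(u_sym, j, "vb")
            ins.append(Instruction("mul", "va", (fw, fu)))
            factor = "va"
        ins.append(Instruction("mac", "F", (c, factor)))

    variables = ["va", "vb"] + ([] if u_feature else ["vu"])
    return InstructionProgram(
        workspace=_ws(features, tuple(params), tuple(variables)),
        instructions=tuple(ins),
        max_instructions=max(6, len(ins)),
    )


def wb97mv_x_program(u_feature: bool = True) -> tuple[InstructionProgram, dict]:
    """The wB97M-V exchange power series as a program, with its parameters."""
    terms = WB97MV_TERM_SUBSETS["x"]
    prog = power_series_program(terms, prefix="x_", u_feature=u_feature)
    params = {f"x_c{t}": _WB97MV["coefficients"]["x"][t] for t in terms}
    if not u_feature:
        params["x_g"] = _WB97MV["gamma"]["x"]
    return prog, params


def wb97mv_functional() -> tuple[SymbolicFunctional, dict]:
    """All three wB97M-V channels as programs over (x2, w), with parameters."""
    programs, params = {}, {}
    for ch in CHANNELS:
        terms = WB97MV_TERM_SUBSETS[ch]
        programs[ch] = power_series_program(terms, prefix=f"{ch}_", u_feature=False)
        for t in terms:
            params[f"{ch}_c{t}"] = _WB97MV["coefficients"][ch][t]
        params[f"{ch}_g"] = _WB97MV["gamma"][ch]
    return SymbolicFunctional(programs), params


def _gas22_x_program() -> tuple[InstructionProgram, dict]:
    tab = _GAS22["x"]
    prog = InstructionProgram(
        workspace=_ws(("x2", "w"), ("x_a0", "x_a1", "x_a2", "x_g"), ("v0",)),
        instructions=(
            Instruction("transform", "v0", ("x2",), gamma="x_g"),
            Instruction("mac", "F", ("x_a1", "v0")),
            Instruction("mac", "F", ("x_a2", "w")),
            Instruction("add", "F", ("F", "x_a0")),
        ),
        max_instructions=6,
    )
    return prog, {"x_a0": tab["c0"], "x_a1": tab["c_u"], "x_a2": tab["c_w"], "x_g": tab["gamma"]}


def _gas22_css_program() -> tuple[InstructionProgram, dict]:
    tab = _GAS22["css"]
    prog = InstructionProgram(
        workspace=_ws(("x2", "w"), ("s_b1", "s_b2", "s_b3", "s_b4", "s_g"), ("v0", "v1", "v2")),
        instructions=(
            Instruction("transform", "v0", ("x2",), gamma="s_g"),
            Instruction("add", "F", ("F", "v0")),
            Instruction("mac", "F", ("s_b1", "w")),
            Instruction("power", "v1", ("w",), exponent=Fraction(2)),
            Instruction("mac", "F", ("s_b2", "v1")),
            Instruction("power", "v1", ("v0",), exponent=Fraction(6)),
            Instruction("mac", "F", ("s_b3", "v1")),
            Instruction("power", "v2", ("w",), exponent=Fraction(4)),
            Instruction("mul", "v2", ("v2", "v1")),
            Instruction("mac", "F", ("s_b4", "v2")),
        ),
        max_instructions=12,
    )
    return prog, {"s_b1": tab["c_w"], "s_b2": tab["c_w2"], "s_b3": tab["c_u6"],
                  "s_b4": tab["c_w4u6"], "s_g": tab["gamma"]}


def _gas22_cos_program() -> tuple[InstructionProgram, dict]:
    tab = _GAS22["cos"]
    e = Fraction(tab["x_exponent"])
    # x**(3/2) from the x2 feature via allowed exponents: ((x2)**(1/2))**3)**(1/2);
    # the alternative x**(2/3) reading is (x2)**(1/3).
    if e == Fraction(3, 2):
        xe_chain = (
            Instruction("power", "v0", ("x2",), exponent=Fraction(1, 2)),
            Instruction("power", "v0", ("v0",), exponent=Fraction(3)),
            Instruction("power", "v0", ("v0",), exponent=Fraction(1, 2)),
        )
    elif e == Fraction(2, 3):
        xe_chain = (Instruction("power", "v0", ("x2",), exponent=Fraction(1, 3)),)
    else:
        raise ValueError(f"unsupported opposite-spin x exponent {e}")
    prog = InstructionProgram(
        workspace=_ws(("x2", "w"), ("o_d0", "o_d1", "o_d2", "o_d3", "o_d4"), ("v0", "v1", "v2")),
        instructions=xe_chain + (
            Instruction("power", "v1", ("w",), exponent=Fraction(2)),
            Instruction("mac", "F", ("o_d1", "v1")),
            Instruction("power", "v2", ("w",), exponent=Fraction(6)),
            Instruction("mac", "F", ("o_d2", "v2")),
            Instruction("mul", "v2", ("v2", "v0")),
            Instruction("mac", "F", ("o_d3", "v2")),
            Instruction("mul", "v1", ("v1", "v0")),
            Instruction("mac", "F", ("o_d4", "v1")),
            Instruction("add", "F", ("F", "o_d0")),
        ),
        max_instructions=14,
    )
    return prog, {"o_d0": tab["c0"], "o_d1": tab["c_w2"], "o_d2": tab["c_w6"],
                  "o_d3": tab["c_w6x"], "o_d4": tab["c_w2x"]}


def gas22_functional() -> tuple[SymbolicFunctional, dict]:
    """The GAS22 triple as instruction programs, with its shipped parameters."""
    px, vx = _gas22_x_program()
    ps, vs = _gas22_css_program()
    po, vo = _gas22_cos_program()
    return SymbolicFunctional({"x": px, "css": ps, "cos": po}), {**vx, **vs, **vo}
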