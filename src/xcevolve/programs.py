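"""Instruction-program representation of exchange-correlation enhancement factors.

An enhancement factor (F_x, F_c-ss or F_c-os) is represented as a short,
ordered list of elementary instructions operating on a *workspace* of named
symbols.  The workspace holds three kinds of symbols:

* **features** — the inputs of the functional form (e.g. the squared reduced
  density gradient ``x2``, or the kinetic-energy-density feature ``w``);
* **parameters** — scalar constants determined later by fitting to data;
* **variables** — intermediate storage, all initialized to zero before
  execution.  The distinguished variable ``F`` holds the result: after all
  instructions have executed, the value of ``F`` *is* the enhancement factor.

The instruction set consists of the binary arithmetic operations
``s = p + q``, ``s = p - q``, ``s = p * q``, ``s = p / q``, the
multiply-accumulate ``s = s + p * q`` (the only operation that implicitly
reads its own output), integer and fractional powers
``s = p**n, n in {2, 3, 4, 6, 1/2, 1/3}``, and the finite-domain transform
``s = g*p / (1 + g*p)`` whose parameter ``g`` (gamma) is bound to the
instruction itself.  This mirrors how a computer program evaluates a
density functional, and is the search space explored by the evolutionary
machinery in :mod:`xcevolve.evolution`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy

__all__ = [
    "Symbol",
    "Instruction",
    "InstructionProgram",
    "SymbolicFunctional",
    "OPS",
    "BINARY_OPS",
    "UNARY_OPS",
    "POWER_EXPONENTS",
    "CHANNELS",
    "RESULT_VARIABLE",
    "execute_program",
    "validate_program",
    "render_expression",
    "program_to_sympy",
    "make_workspace",
    "empty_functional",
]

#: Name of the distinguished output variable.
RESULT_VARIABLE = "F"

#: The three enhancement-factor channels: exchange, same-spin correlation,
#: opposite-spin correlation.
CHANNELS = ("x", "css", "cos")

#: Admissible exponents for the power operation.
POWER_EXPONENTS = (
    Fraction(2),
    Fraction(3),
    Fraction(4),
    Fraction(6),
    Fraction(1, 2),
    Fraction(1, 3),
)

#: op tag -> arity of explicit inputs.
BINARY_OPS = ("add", "sub", "mul", "div", "mac")
UNARY_OPS = ("power", "transform")
OPS = BINARY_OPS + UNARY_OPS

_ARITY = {**{op: 2 for op in BINARY_OPS}, **{op: 1 for op in UNARY_OPS}}


@dataclass(frozen=True)
class Symbol:
    """A named workspace slot of kind ``feature``, ``parameter`` or ``variable``."""

    name: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("feature", "parameter", "variable"):
            raise ValueError(f"unknown symbol kind {self.kind!r}")


@dataclass(frozen=True)
class Instruction:
    """One executable statement writing to a variable of the workspace.

    ``exponent`` is set only for ``power``; ``gamma`` (the name of the bound
    parameter of the finite-domain transform) only for ``transform``.
    """

    op: str
    output: str
    inputs: tuple[str, ...]
    exponent: Fraction | None = None
    gamma: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        if self.exponent is not None:
            object.__setattr__(self, "exponent", Fraction(self.exponent))

    def referenced(self) -> tuple[str, ...]:
        """All symbol names this instruction touches (output, inputs, gamma)."""
        names = (self.output,) + self.inputs
        if self.gamma is not None:
            names += (self.gamma,)
        return names

    def to_dict(self) -> dict:
        d: dict = {"op": self.op, "output": self.output, "inputs": list(self.inputs)}
        if self.exponent is not None:
            d["exponent"] = str(self.exponent)
        if self.gamma is not None:
            d["bound_parameter"] = self.gamma
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Instruction":
        exponent = d.get("exponent")
        return cls(
            op=d["op"],
            output=d["output"],
            inputs=tuple(d["inputs"]),
            exponent=Fraction(exponent) if exponent is not None else None,
            gamma=d.get("bound_parameter"),
        )


@dataclass(frozen=True)
class InstructionProgram:
    """An ordered instruction list plus its workspace declaration."""

    workspace: tuple[Symbol, ...]
    instructions: tuple[Instruction, ...] = ()
    max_instructions: int = 6

    def __post_init__(self) -> None:
        object.__setattr__(self, "workspace", tuple(self.workspace))
        object.__setattr__(self, "instructions", tuple(self.instructions))

    # -- workspace helpers -------------------------------------------------
    def symbols(self, kind: str | None = None) -> tuple[Symbol, ...]:
        if kind is None:
            return self.workspace
        return tuple(s for s in self.workspace if s.kind == kind)

    def names(self, kind: str | None = None) -> tuple[str, ...]:
        return tuple(s.name for s in self.symbols(kind))

    @property
    def kind_of(self) -> dict[str, str]:
        return {s.name: s.kind for s in self.workspace}

    def with_instructions(self, instructions: Iterable[Instruction]) -> "InstructionProgram":
        return replace(self, instructions=tuple(instructions))

    # -- validation --------------------------------------------------------
    def validate(self) -> list[str]:
        return validate_program(self)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "workspace": [{"name": s.name, "kind": s.kind} for s in self.workspace],
            "instructions": [i.to_dict() for i in self.instructions],
            "max_instructions": self.max_instructions,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "InstructionProgram":
        return cls(
            workspace=tuple(Symbol(s["name"], s["kind"]) for s in d["workspace"]),
            instructions=tuple(Instruction.from_dict(i) for i in d["instructions"]),
            max_instructions=int(d["max_instructions"]),
        )

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "InstructionProgram":
        return cls.from_dict(json.loads(s))


def validate_program(program: InstructionProgram) -> list[str]:
    """Check every structural invariant; return a list of human-readable violations.

    Total function: never raises, an empty list means the program is valid.
    """
    violations: list[str] = []
    names = [s.name for s in program.workspace]
    if len(set(names)) != len(names):
        violations.append("workspace: duplicate symbol names")
    kind_of = program.kind_of
    if kind_of.get(RESULT_VARIABLE) != "variable":
        violations.append(f"workspace: missing result variable {RESULT_VARIABLE!r}")
    if len(program.instructions) > program.max_instructions:
        violations.append(
            f"program: {len(program.instructions)} instructions exceed cap "
            f"{program.max_instructions}"
        )
    for i, ins in enumerate(program.instructions):
        where = f"instruction {i} ({ins.op})"
        if ins.op not in OPS:
            violations.append(f"{where}: unknown op")
            continue
        for name in ins.referenced():
            if name not in kind_of:
                violations.append(f"{where}: undeclared symbol {name!r}")
        if kind_of.get(ins.output) not in (None, "variable"):
            violations.append(f"{where}: output {ins.output!r} is not a variable")
        if len(ins.inputs) != _ARITY[ins.op]:
            violations.append(
                f"{where}: arity {len(ins.inputs)} != {_ARITY[ins.op]}"
            )
        if ins.op == "power":
            if ins.exponent not in POWER_EXPONENTS:
                violations.append(f"{where}: exponent {ins.exponent} not allowed")
        elif ins.exponent is not None:
            violations.append(f"{where}: exponent given for non-power op")
        if ins.op == "transform":
            if ins.gamma is None:
                violations.append(f"{where}: transform without bound parameter")
            elif kind_of.get(ins.gamma) not in (None, "parameter"):
                violations.append(
                    f"{where}: bound parameter {ins.gamma!r} is not a parameter"
                )
        elif ins.gamma is not None:
            violations.append(f"{where}: bound parameter given for non-transform op")
    return violations


def _require_valid(program: InstructionProgram) -> None:
    violations = validate_program(program)
    if violations:
        raise ValueError("invalid program: " + "; ".join(violations))


def execute_program(
    program: InstructionProgram,
    feature_values: Mapping[str, object],
    parameter_values: Mapping[str, object],
    return_valid: bool = False,
):
    """Execute the program elementwise over grid points and return ``F``.

    ``feature_values`` maps feature names to arrays over grid points (last
    axis = points); ``parameter_values`` maps parameter names to scalars, or
    to column vectors of shape ``(k, 1)`` to evaluate ``k`` parameter sets in
    one batched pass.  Variables start at zero; instructions execute in list
    order; features and parameters are never written.

    With ``return_valid=True`` also returns a validity flag (reduced over the
    grid-point axis): any division by ~0, fractional power of a negative
    argument, or other non-finite intermediate marks the whole evaluation
    (respectively the affected batch row) invalid instead of raising.
    """
    _require_valid(program)
    kind_of = program.kind_of
    values: dict[str, object] = {}
    shapes = []
    for sym in program.workspace:
        if sym.kind == "feature":
            if sym.name not in feature_values:
                raise ValueError(f"missing feature {sym.name!r}")
            v = np.asarray(feature_values[sym.name], dtype=float)
            values[sym.name] = v
            shapes.append(v.shape)
        elif sym.kind == "parameter":
            if sym.name not in parameter_values:
                raise ValueError(f"missing parameter {sym.name!r}")
            v = np.asarray(parameter_values[sym.name], dtype=float)
            values[sym.name] = v
            shapes.append(v.shape)
        else:
            values[sym.name] = np.float64(0.0)
    target_shape = np.broadcast_shapes(*shapes) if shapes else ()

    mask: object = np.True_
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for ins in program.instructions:
            a = values[ins.inputs[0]]
            if ins.op == "add":
                val = a + values[ins.inputs[1]]
            elif ins.op == "sub":
                val = a - values[ins.inputs[1]]
            elif ins.op == "mul":
                val = a * values[ins.inputs[1]]
            elif ins.op == "div":
                val = a / values[ins.inputs[1]]
            elif ins.op == "mac":
                val = values[ins.output] + a * values[ins.inputs[1]]
            elif ins.op == "power":
                e = ins.exponent
                if e.denominator == 1:
                    val = np.power(a, int(e))
                else:
                    # fractional power of a negative argument -> nan (invalid)
                    val = np.power(a, float(e))
            else:  # transform
                g = values[ins.gamma]
                ga = g * a
                val = ga / (1.0 + ga)
            val = np.asarray(val, dtype=float)
            mask = np.logical_and(mask, np.isfinite(val))
            values[ins.output] = val

    result = np.broadcast_to(
        np.asarray(values[RESULT_VARIABLE], dtype=float), target_shape
    ).copy()
    if not return_valid:
        return result
    mask = np.broadcast_to(np.asarray(mask), target_shape)
    valid = mask.all(axis=-1) if mask.ndim else bool(mask)
    return result, valid


def program_to_sympy(
    program: InstructionProgram, simplify: bool = False
) -> sympy.Expr:
    """Closed-form expression for ``F`` obtained by forward substitution."""
    _require_valid(program)
    values: dict[str, sympy.Expr] = {}
    for sym in program.workspace:
        if sym.kind == "variable":
            values[sym.name] = sympy.Integer(0)
        else:
            values[sym.name] = sympy.Symbol(sym.name)
    for ins in program.instructions:
        a = values[ins.inputs[0]]
        if ins.op == "add":
            val = a + values[ins.inputs[1]]
        elif ins.op == "sub":
            val = a - values[ins.inputs[1]]
        elif ins.op == "mul":
            val = a * values[ins.inputs[1]]
        elif ins.op == "div":
            val = a / values[ins.inputs[1]]
        elif ins.op == "mac":
            val = values[ins.output] + a * values[ins.inputs[1]]
        elif ins.op == "power":
            val = a ** sympy.Rational(ins.exponent.numerator, ins.exponent.denominator)
        else:
            g = values[ins.gamma]
            val = g * a / (1 + g * a)
        values[ins.output] = val
    expr = values[RESULT_VARIABLE]
    if simplify:
        expr = sympy.cancel(sympy.together(expr))
    return expr


def render_expression(program: InstructionProgram, simplify: bool = False) -> str:
    """Human-readable closed-form string for the program's readout."""
    return str(program_to_sympy(program, simplify=simplify))


def make_workspace(
    features: Sequence[str] = ("x2",),
    n_parameters: int = 4,
    n_variables: int = 3,
    prefix: str = "",
) -> tuple[Symbol, ...]:
    """Build a standard workspace declaration.

    ``n_variables`` counts the result variable ``F``: e.g. the canonical
    single-feature workspace of one feature, four parameters and three
    variables is ``(x2, p0..p3, v0, v1, F)``.
    """
    if n_variables < 1:
        raise ValueError("need at least the result variable")
    ws = [Symbol(f, "feature") for f in features]
    ws += [Symbol(f"{prefix}p{i}", "parameter") for i in range(n_parameters)]
    ws += [Symbol(f"{prefix}v{i}", "variable") for i in range(n_variables - 1)]
    ws.append(Symbol(RESULT_VARIABLE, "variable"))
    return tuple(ws)


@dataclass(frozen=True)
class SymbolicFunctional:
    """Triple of instruction programs — one per enhancement-factor channel.

    The unit of evolution: channels ``x`` (exchange), ``css`` (same-spin
    correlation) and ``cos`` (opposite-spin correlation).  Free scalar
    parameters are shared by name across channels.
    """

    programs: Mapping[str, InstructionProgram]

    def __post_init__(self) -> None:
        progs = dict(self.programs)
        if set(progs) != set(CHANNELS):
            raise ValueError(f"programs must cover channels {CHANNELS}")
        object.__setattr__(self, "programs", progs)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        """Deduplicated union of parameter symbols, in stable channel order."""
        seen: dict[str, None] = {}
        for ch in CHANNELS:
            for name in self.programs[ch].names("parameter"):
                seen.setdefault(name)
        return tuple(seen)

    def validate(self) -> list[str]:
        out = []
        for ch in CHANNELS:
            out += [f"{ch}: {v}" for v in self.programs[ch].validate()]
        return out

    def to_dict(self) -> dict:
        return {ch: self.programs[ch].to_dict() for ch in CHANNELS}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SymbolicFunctional":
        return cls({ch: InstructionProgram.from_dict(d[ch]) for ch in CHANNELS})

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "SymbolicFunctional":
        return cls.from_dict(json.loads(s))


def empty_functional(
    features: Sequence[str] = ("x2",),
    n_parameters: int = 4,
    n_variables: int = 3,
    max_instructions: int = 6,
    shared_parameters: bool = False,
) -> SymbolicFunctional:
    """The functional with no instructions: every channel outputs zero.

    By default each channel owns a disjoint parameter pool (prefixed by the
    channel name); ``shared_parameters=True`` gives all channels one pool.
    """
    programs = {}
    for ch in CHANNELS:
        prefix = "" if shared_parameters else f"{ch}_"
        programs[ch] = InstructionProgram(
            workspace=make_workspace(features, n_parameters, n_variables, prefix),
            instructions=(),
            max_instructions=max_instructions,
        )
    return SymbolicFunctional(programs)
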