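"""Mutation operators over symbolic functionals.

A child is produced from a parent by choosing one enhancement-factor
channel uniformly at random and applying exactly one of four rules to its
instruction program: *insert* a new instruction, *remove* an existing one,
*change the operation* of an instruction (within its arity class), or
*change one argument* of an instruction.  All sampling distributions are
uniform over the legal choices; rule probabilities are configurable.

Parameters bound as a transform gamma are reserved: they are not offered
as ordinary instruction arguments.  A search space may designate a fixed
gamma pool (e.g. one of four workspace parameters reserved for the
transform, with the rest free as arguments); without one, a newly inserted
transform binds a not-yet-reserved parameter while the budget allows and
reuses an existing gamma otherwise.
If the sampled rule is inapplicable (e.g. removal from an empty
program) the rule is resampled a bounded number of times; if nothing
applies, a flagged no-op copy of the parent is returned so the caller can
keep population bookkeeping faithful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .programs import (
    BINARY_OPS,
    CHANNELS,
    OPS,
    POWER_EXPONENTS,
    Instruction,
    InstructionProgram,
    SymbolicFunctional,
)

__all__ = ["MutationConfig", "MutationRecord", "RULES", "apply_rule", "mutate_functional"]

RULES = ("insert", "remove", "change_op", "change_arg")


@dataclass(frozen=True)
class MutationConfig:
    rule_weights: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.25 for r in RULES}
    )
    allowed_ops: tuple[str, ...] = OPS
    allowed_exponents: tuple[Fraction, ...] = POWER_EXPONENTS
    channels: tuple[str, ...] = CHANNELS
    #: parameters designated as transform gammas: bindable by transforms only,
    #: never offered as ordinary arguments.  None -> dynamic reservation (any
    #: parameter may be bound; once bound it leaves the argument pool).
    gamma_pool: tuple[str, ...] | None = None
    max_retries: int = 16

    def __post_init__(self) -> None:
        w = dict(self.rule_weights)
        if set(w) - set(RULES):
            raise ValueError(f"unknown rules {set(w) - set(RULES)}")
        total = sum(w.values())
        if not np.isclose(total, 1.0):
            raise ValueError("rule weights must sum to 1")
        object.__setattr__(self, "rule_weights", w)
        if not self.allowed_ops or set(self.allowed_ops) - set(OPS):
            raise ValueError("allowed_ops must be a nonempty subset of the op set")
        exps = tuple(Fraction(e) for e in self.allowed_exponents)
        if set(exps) - set(POWER_EXPONENTS):
            raise ValueError("allowed_exponents outside the admissible set")
        object.__setattr__(self, "allowed_exponents", exps)
        if not self.channels or set(self.channels) - set(CHANNELS):
            raise ValueError("channels must be a nonempty subset of the channel set")


@dataclass(frozen=True)
class MutationRecord:
    channel: str
    rule: str | None
    noop: bool


def _choice(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(len(seq)))]


def _reserved_gammas(program: InstructionProgram, config: "MutationConfig") -> set[str]:
    bound = {ins.gamma for ins in program.instructions if ins.gamma is not None}
    if config.gamma_pool is not None:
        bound |= set(config.gamma_pool)
    return bound


def _argument_pool(program: InstructionProgram, config: "MutationConfig") -> list[str]:
    """Symbols legal as instruction inputs: everything except reserved gammas."""
    reserved = _reserved_gammas(program, config)
    return [s.name for s in program.workspace if s.name not in reserved]


def _sample_gamma(program: InstructionProgram, rng, config: "MutationConfig") -> str | None:
    """A parameter to bind as transform gamma.

    With a designated ``gamma_pool`` the choice is uniform over the pool;
    otherwise a not-yet-bound parameter is preferred (fresh gamma while the
    budget allows), falling back to reuse of an already bound one.
    """
    if config.gamma_pool is not None:
        pool = [p for p in config.gamma_pool if p in program.names("parameter")]
        return _choice(rng, pool) if pool else None
    params = list(program.names("parameter"))
    if not params:
        return None
    bound = {ins.gamma for ins in program.instructions if ins.gamma is not None}
    fresh = [p for p in params if p not in bound]
    return _choice(rng, fresh if fresh else sorted(bound))


def _build_instruction(program, op, rng, config) -> Instruction | None:
    variables = list(program.names("variable"))
    pool = _argument_pool(program, config)
    output = _choice(rng, variables)
    if op in BINARY_OPS:
        return Instruction(op, output, (_choice(rng, pool), _choice(rng, pool)))
    if op == "power":
        return Instruction(op, output, (_choice(rng, pool),),
                           exponent=_choice(rng, config.allowed_exponents))
    gamma = _sample_gamma(program, rng, config)
    if gamma is None:
        return None
    return Instruction("transform", output, (_choice(rng, pool),), gamma=gamma)


def apply_rule(
    program: InstructionProgram,
    rule: str,
    rng: np.random.Generator,
    config: MutationConfig = MutationConfig(),
) -> InstructionProgram | None:
    """Apply one mutation rule; ``None`` when the rule is inapplicable."""
    ins = list(program.instructions)

    if rule == "insert":
        if len(ins) >= program.max_instructions:
            return None
        op = _choice(rng, config.allowed_ops)
        new = _build_instruction(program, op, rng, config)
        if new is None:
            return None
        ins.insert(int(rng.integers(len(ins) + 1)), new)
        return program.with_instructions(ins)

    if not ins:
        return None
    idx = int(rng.integers(len(ins)))

    if rule == "remove":
        del ins[idx]
        return program.with_instructions(ins)

    if rule == "change_op":
        cur = ins[idx]
        same_class = BINARY_OPS if cur.op in BINARY_OPS else ("power", "transform")
        options = [o for o in config.allowed_ops if o in same_class and o != cur.op]
        if cur.op == "power" and len(config.allowed_exponents) > 1:
            options.append("power")  # re-draw of the exponent counts as an op change
        if not options:
            return None
        op = _choice(rng, options)
        if op in BINARY_OPS:
            new = Instruction(op, cur.output, cur.inputs)
        elif op == "power":
            exps = [e for e in config.allowed_exponents if e != cur.exponent] \
                or list(config.allowed_exponents)
            new = Instruction("power", cur.output, cur.inputs[:1],
                              exponent=_choice(rng, exps))
        else:
            gamma = _sample_gamma(program, rng, config)
            if gamma is None:
                return None
            new = Instruction("transform", cur.output, cur.inputs[:1], gamma=gamma)
        ins[idx] = new
        return program.with_instructions(ins)

    if rule == "change_arg":
        for _ in range(config.max_retries):
            idx = int(rng.integers(len(ins)))
            cur = ins[idx]
            slots = [("input", i) for i in range(len(cur.inputs))] + [("output", 0)]
            if cur.gamma is not None:
                slots.append(("gamma", 0))
            kind, i = _choice(rng, slots)
            if kind == "output":
                cands = [v for v in program.names("variable") if v != cur.output]
                if not cands:
                    continue
                new = Instruction(cur.op, _choice(rng, cands), cur.inputs,
                                  exponent=cur.exponent, gamma=cur.gamma)
            elif kind == "input":
                cands = [s for s in _argument_pool(program, config) if s != cur.inputs[i]]
                if not cands:
                    continue
                inputs = list(cur.inputs)
                inputs[i] = _choice(rng, cands)
                new = Instruction(cur.op, cur.output, tuple(inputs),
                                  exponent=cur.exponent, gamma=cur.gamma)
            else:
                gammas = (config.gamma_pool if config.gamma_pool is not None
                          else program.names("parameter"))
                cands = [p for p in gammas if p != cur.gamma]
                if not cands:
                    continue
                new = Instruction(cur.op, cur.output, cur.inputs,
                                  exponent=cur.exponent, gamma=_choice(rng, cands))
            ins[idx] = new
            return program.with_instructions(ins)
        return None

    raise ValueError(f"unknown rule {rule!r}")


def mutate_functional(
    parent: SymbolicFunctional,
    config: MutationConfig,
    rng: np.random.Generator,
) -> tuple[SymbolicFunctional, MutationRecord]:
    """One mutation step: pick a channel uniformly, apply one rule.

    Returns the child (always valid) and a record of what was applied; the
    parent is never modified.  When no rule applies within the retry budget
    the child is a copy of the parent flagged as a no-op.
    """
    channel = _choice(rng, config.channels)
    program = parent.programs[channel]
    rules = list(config.rule_weights)
    probs = np.array([config.rule_weights[r] for r in rules])
    for _ in range(config.max_retries):
        rule = rules[int(rng.choice(len(rules), p=probs))]
        mutated = apply_rule(program, rule, rng, config)
        if mutated is not None and not mutated.validate():
            programs = dict(parent.programs)
            programs[channel] = mutated
            return SymbolicFunctional(programs), MutationRecord(channel, rule, False)
    return (
        SymbolicFunctional(dict(parent.programs)),
        MutationRecord(channel, None, True),
    )
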