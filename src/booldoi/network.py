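"""Synchronous Boolean networks: model, rule-file IO and simulation.

A Boolean network consists of ``N`` nodes, each carrying a binary state
``sigma_i(t)``; node ``i`` updates synchronously via a transfer function
``F_i`` of the states of its ordered input list (its neighbourhood) at
time ``t - 1``.  Every transfer function can be materialized as a
complete look-up table (LUT) whose rows are ordered by reading the input
tuple as a binary number with the first input as the most significant
bit.

Environmental inputs (nodes that never receive a rule) are modelled as
identity self-loops of arity 1, which keeps their state time-invariant
under the synchronous update while every node remains governed by a
transfer function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .expr import (
    And,
    Const,
    Expr,
    ExpressionError,
    Not,
    Or,
    Var,
    evaluate,
    parse_expression,
    to_string,
    variables,
)

__all__ = [
    "TransferFunction",
    "BooleanNetwork",
    "RuleFileError",
    "parse_rules",
    "write_rules",
    "write_lut_table",
    "read_lut_table",
    "identity_rule",
    "materialize_lut",
    "step",
    "trajectory",
    "config_to_json",
    "config_from_json",
]


class RuleFileError(ValueError):
    """Raised for syntactically invalid rule files (reports the line)."""


def input_tuple(row: int, k: int) -> tuple[int, ...]:
    """Bits of LUT row ``row`` for arity ``k`` (first input most significant)."""
    return tuple((row >> (k - 1 - j)) & 1 for j in range(k))


def row_index(bits: Sequence[int], k: int) -> int:
    idx = 0
    for b in bits:
        idx = (idx << 1) | int(b)
    return idx


@dataclass
class TransferFunction:
    """A node's update rule, as an expression, a complete LUT, or both.

    ``lut`` is a tuple of ``2**arity`` output bits, one per input row in
    the canonical row order.  When both forms are present they must agree
    on every row (checked exhaustively on validation for arity <= 12).
    """

    arity: int
    expression: Expr | None = None
    lut: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.expression is None and self.lut is None:
            raise ValueError("transfer function needs an expression or a LUT")
        if self.lut is not None:
            self.lut = tuple(int(b) for b in self.lut)
            if len(self.lut) != 2**self.arity:
                raise ValueError(
                    f"LUT has {len(self.lut)} rows, expected {2 ** self.arity}"
                )
            if any(b not in (0, 1) for b in self.lut):
                raise ValueError("LUT outputs must be bits")


def materialize_lut(
    tf: TransferFunction, ordered_inputs: Sequence[str]
) -> tuple[int, ...]:
    """Complete LUT of ``tf`` over ``ordered_inputs``, in canonical row order.

    Idempotent when the LUT is already present; otherwise evaluates the
    expression on every one of the ``2**k`` input tuples.
    """
    if tf.lut is not None:
        return tf.lut
    assert tf.expression is not None
    missing = set(variables(tf.expression)) - set(ordered_inputs)
    if missing:
        raise ExpressionError(
            f"expression references symbols not among inputs: {sorted(missing)}"
        )
    k = len(ordered_inputs)
    rows = []
    for r in range(2**k):
        env = dict(zip(ordered_inputs, input_tuple(r, k)))
        rows.append(evaluate(tf.expression, env))
    return tuple(rows)


def identity_rule(node: str) -> TransferFunction:
    """The arity-1 identity self-loop rule used for environmental inputs."""
    return TransferFunction(arity=1, expression=Var(node), lut=(0, 1))


class BooleanNetwork:
    """A synchronously updated Boolean network.

    Parameters
    ----------
    nodes
        Ordered node identifiers (case-sensitive strings, no whitespace).
    inputs
        Mapping node -> ordered input list (the neighbourhood ``N_i``).
    rules
        Mapping node -> :class:`TransferFunction`.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        inputs: Mapping[str, Sequence[str]],
        rules: Mapping[str, TransferFunction],
    ) -> None:
        self.nodes: list[str] = list(nodes)
        self.inputs: dict[str, list[str]] = {n: list(inputs[n]) for n in self.nodes}
        self.rules: dict[str, TransferFunction] = dict(rules)
        self._lut_cache: dict[str, tuple[int, ...]] = {}
        self._compiled: _CompiledNetwork | None = None
        self.validate()

    @property
    def N(self) -> int:
        return len(self.nodes)

    def degree(self, node: str) -> int:
        """In-degree ``k_i`` of ``node``."""
        return len(self.inputs[node])

    def validate(self) -> None:
        declared = set(self.nodes)
        if len(declared) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        for n in self.nodes:
            if any(ch.isspace() for ch in n):
                raise ValueError(f"node identifier {n!r} contains whitespace")
            if n not in self.rules:
                raise ValueError(f"node {n!r} has no rule")
            ins = self.inputs[n]
            if len(set(ins)) != len(ins):
                raise ValueError(f"duplicate inputs for node {n!r}")
            undeclared = set(ins) - declared
            if undeclared:
                raise ValueError(f"inputs of {n!r} not declared: {sorted(undeclared)}")
            tf = self.rules[n]
            if tf.arity != len(ins):
                raise ValueError(
                    f"arity {tf.arity} of rule for {n!r} != {len(ins)} inputs"
                )
            if tf.expression is not None and tf.lut is not None and tf.arity <= 12:
                if materialize_lut(
                    TransferFunction(tf.arity, expression=tf.expression), ins
                ) != tf.lut:
                    raise ValueError(f"expression and LUT disagree for node {n!r}")

    def lut(self, node: str) -> tuple[int, ...]:
        """Materialized (and cached) LUT of ``node``."""
        if node not in self._lut_cache:
            self._lut_cache[node] = materialize_lut(self.rules[node], self.inputs[node])
        return self._lut_cache[node]

    def is_identity_input(self, node: str) -> bool:
        """True for nodes governed by the arity-1 identity self-loop."""
        return self.inputs[node] == [node] and self.lut(node) == (0, 1)

    def compiled(self) -> "_CompiledNetwork":
        if self._compiled is None:
            self._compiled = _CompiledNetwork.from_network(self)
        return self._compiled

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BooleanNetwork(N={self.N}, nodes={self.nodes!r})"


# --------------------------------------------------------------------------
# Rule-file dialects


def _parse_generic(text: str) -> list[tuple[str, str, int]]:
    entries = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise RuleFileError(f"line {lineno}: expected 'name = expression'")
        name, rhs = line.split("=", 1)
        name = name.strip()
        if not name or any(ch.isspace() for ch in name):
            raise RuleFileError(f"line {lineno}: invalid node name {name!r}")
        entries.append((name, rhs.strip(), lineno))
    return entries


def _parse_cell_collective(text: str) -> list[tuple[str, str, int]]:
    entries = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if lineno == 1 and line.lower().replace(" ", "") in (
            "targets,factors",
            "target,factors",
            "targets,factor",
        ):
            continue
        if "," not in line:
            raise RuleFileError(f"line {lineno}: expected 'target, factors'")
        name, rhs = line.split(",", 1)
        name = name.strip()
        if not name or any(ch.isspace() for ch in name):
            raise RuleFileError(f"line {lineno}: invalid node name {name!r}")
        entries.append((name, rhs.strip(), lineno))
    return entries


def parse_rules(text: str, dialect: str = "generic") -> BooleanNetwork:
    """Parse a rule file into a :class:`BooleanNetwork`.

    Dialects: ``generic`` ("name = expression" lines, '#' comments) and
    ``cell_collective`` (two-column "targets, factors" lines with an
    optional header).  Symbols that appear only as inputs become
    environmental input nodes with the implicit identity self-loop rule.
    """
    if dialect == "generic":
        entries = _parse_generic(text)
    elif dialect == "cell_collective":
        entries = _parse_cell_collective(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    rules: dict[str, TransferFunction] = {}
    inputs: dict[str, list[str]] = {}
    order: list[str] = []
    for name, rhs, lineno in entries:
        if name in rules:
            raise RuleFileError(f"line {lineno}: duplicate rule for node {name!r}")
        try:
            expr = parse_expression(rhs)
        except ExpressionError as exc:
            raise RuleFileError(f"line {lineno}: {exc}") from exc
        ins = variables(expr)
        rules[name] = TransferFunction(arity=len(ins), expression=expr)
        inputs[name] = ins
        order.append(name)

    # Symbols used only as inputs: environmental inputs with identity rules.
    for name in list(order):
        for j in inputs[name]:
            if j not in rules:
                rules[j] = identity_rule(j)
                inputs[j] = [j]
                order.append(j)
    return BooleanNetwork(order, inputs, rules)


def _expression_from_lut(
    lut: Sequence[int], ordered_inputs: Sequence[str]
) -> Expr:
    """A DNF-of-rows expression semantically equal to ``lut``.

    Constant functions are written as tautologies/contradictions over the
    declared inputs so that parsing the output reproduces the input list
    (and hence the arity) exactly.
    """
    k = len(ordered_inputs)
    if k == 0:
        return Const(int(lut[0]))
    ones = [r for r in range(2**k) if lut[r]]
    if not ones:  # contradiction mentioning every input
        clauses = tuple(And((Var(x), Not(Var(x)))) for x in ordered_inputs)
        return clauses[0] if k == 1 else Or(clauses)
    if len(ones) == 2**k:  # tautology mentioning every input
        terms = tuple(Or((Var(x), Not(Var(x)))) for x in ordered_inputs)
        return terms[0] if k == 1 else And(terms)
    clauses = []
    for r in ones:
        bits = input_tuple(r, k)
        lits = tuple(
            Var(x) if b else Not(Var(x)) for x, b in zip(ordered_inputs, bits)
        )
        clauses.append(lits[0] if k == 1 else And(lits))
    return clauses[0] if len(clauses) == 1 else Or(tuple(clauses))


def write_rules(net: BooleanNetwork, dialect: str = "generic") -> str:
    """Serialize a network in a rule-file dialect (inverse of parse_rules).

    Nodes with an expression are written verbatim; LUT-only nodes are
    written as the OR of their output-1 rows.
    """
    lines = []
    if dialect == "cell_collective":
        lines.append("targets, factors")
    for n in net.nodes:
        tf = net.rules[n]
        expr = tf.expression
        if expr is None:
            expr = _expression_from_lut(net.lut(n), net.inputs[n])
        rhs = to_string(expr)
        if dialect == "generic":
            lines.append(f"{n} = {rhs}")
        elif dialect == "cell_collective":
            lines.append(f"{n}, {rhs}")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return "\n".join(lines) + "\n"


def write_lut_table(net: BooleanNetwork, node: str) -> str:
    """Serialize one node's LUT: a header naming node and inputs, then rows."""
    ins = net.inputs[node]
    lut = net.lut(node)
    k = len(ins)
    lines = [f"# node: {node}", "# inputs: " + " ".join(ins)]
    for r in range(2**k):
        bits = input_tuple(r, k)
        lines.append(" ".join(str(b) for b in bits) + f" {lut[r]}")
    return "\n".join(lines) + "\n"


def read_lut_table(text: str) -> tuple[str, list[str], tuple[int, ...]]:
    """Parse a LUT file back into (node, ordered inputs, LUT)."""
    node = None
    ins: list[str] = []
    rows: dict[int, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("# node:"):
            node = line.split(":", 1)[1].strip()
            continue
        if line.startswith("# inputs:"):
            ins = line.split(":", 1)[1].split()
            continue
        if line.startswith("#"):
            continue
        parts = line.split()
        bits = [int(b) for b in parts[:-1]]
        if len(bits) != len(ins):
            raise RuleFileError(f"line {lineno}: expected {len(ins)} input bits")
        r = row_index(bits, len(ins))
        if r in rows:
            raise RuleFileError(f"line {lineno}: duplicate LUT row")
        rows[r] = int(parts[-1])
    if node is None:
        raise RuleFileError("missing '# node:' header")
    k = len(ins)
    if sorted(rows) != list(range(2**k)):
        raise RuleFileError(f"LUT incomplete: expected {2 ** k} distinct rows")
    return node, ins, tuple(rows[r] for r in range(2**k))


# --------------------------------------------------------------------------
# Simulation


def _pin_dict(pinned) -> dict[str, int]:
    if pinned is None:
        return {}
    if hasattr(pinned, "pins"):  # SeedSet duck-typing, avoids circular import
        return {i: int(v) for i, v in pinned.pins}
    return {i: int(v) for i, v in dict(pinned).items()}


def step(
    net: BooleanNetwork,
    config: Mapping[str, int],
    pinned=None,
) -> dict[str, int]:
    """One synchronous update; pinned nodes keep their pinned value."""
    pins = _pin_dict(pinned)
    new: dict[str, int] = {}
    for i in net.nodes:
        if i in pins:
            new[i] = pins[i]
            continue
        lut = net.lut(i)
        idx = 0
        for j in net.inputs[i]:
            idx = (idx << 1) | int(config[j])
        new[i] = lut[idx]
    return new


def trajectory(
    net: BooleanNetwork,
    config: Mapping[str, int],
    pinned=None,
    T: int = 10,
) -> list[dict[str, int]]:
    """``[sigma(0), ..., sigma(T)]`` under synchronous update with pinning.

    Pins apply from t = 0 on, so the returned initial configuration has
    pinned nodes overridden to their pinned values.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    pins = _pin_dict(pinned)
    current = {i: pins.get(i, int(config[i])) for i in net.nodes}
    out = [current]
    for _ in range(T):
        current = step(net, current, pins)
        out.append(current)
    return out


def config_to_json(config: Mapping[str, int]) -> str:
    return json.dumps({k: int(v) for k, v in config.items()}, sort_keys=True)


def config_from_json(text: str) -> dict[str, int]:
    return {k: int(v) for k, v in json.loads(text).items()}


# --------------------------------------------------------------------------
# Vectorized ensemble simulation (used by ground truth and the benchmark)


@dataclass
class _CompiledNetwork:
    """Array form of a network for simulating many configurations at once."""

    nodes: list[str]
    index: dict[str, int]
    in_idx: list[np.ndarray]
    luts: list[np.ndarray]
    weights: list[np.ndarray]

    @classmethod
    def from_network(cls, net: BooleanNetwork) -> "_CompiledNetwork":
        index = {n: i for i, n in enumerate(net.nodes)}
        in_idx, luts, weights = [], [], []
        for n in net.nodes:
            ins = net.inputs[n]
            k = len(ins)
            in_idx.append(np.array([index[j] for j in ins], dtype=np.intp))
            luts.append(np.array(net.lut(n), dtype=np.uint8))
            weights.append(2 ** np.arange(k - 1, -1, -1, dtype=np.int64))
        return cls(list(net.nodes), index, in_idx, luts, weights)

    def step_ensemble(self, states: np.ndarray) -> np.ndarray:
        """Synchronous update of a (R, N) uint8 array of configurations."""
        new = np.empty_like(states)
        for i in range(len(self.nodes)):
            if self.in_idx[i].size == 0:
                new[:, i] = self.luts[i][0]
            else:
                rows = states[:, self.in_idx[i]].astype(np.int64) @ self.weights[i]
                new[:, i] = self.luts[i][rows]
        return new
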