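"""Fixture networks and random Boolean network (RBN) generation.

Provides the four-node toy network used throughout the documentation
and tests (three environmental inputs a, b, c and a target node with
rule ``(a AND c) OR (b AND c)``), plain copy chains (on which the
mean-field approximation is exact), and classic N-K random Boolean
networks: each node draws K distinct inputs uniformly and each LUT row
outputs 1 independently with a given bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expr import Var, parse_expression
from .network import BooleanNetwork, TransferFunction, identity_rule

__all__ = ["RBNSpec", "toy_network", "random_network", "chain_network"]


@dataclass(frozen=True)
class RBNSpec:
    """Specification of a random Boolean network ensemble member.

    ``K`` is either a single in-degree for every node or a sequence of
    per-node in-degrees; ``bias`` is the probability that a LUT row
    outputs 1.
    """

    N: int
    K: int | tuple[int, ...] = 2
    bias: float = 0.5
    allow_self_loops: bool = True
    seed: int | None = None

    def degrees(self) -> list[int]:
        ks = [self.K] * self.N if isinstance(self.K, int) else list(self.K)
        if len(ks) != self.N:
            raise ValueError("per-node degree list must have length N")
        return ks

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must be in [0, 1]")
        for k in self.degrees():
            if k < 0 or k > self.N:
                raise ValueError(f"invalid in-degree {k} for N={self.N}")


def toy_network() -> BooleanNetwork:
    """Four-node toy network: inputs a, b, c and d = (a AND c) OR (b AND c).

    The inputs of d are declared in the order [a, b, c], so d's
    materialized LUT has exactly three output-1 rows: (0,1,1), (1,0,1)
    and (1,1,1).
    """
    expr = parse_expression("(a AND c) OR (b AND c)")
    nodes = ["a", "b", "c", "d"]
    inputs = {"a": ["a"], "b": ["b"], "c": ["c"], "d": ["a", "b", "c"]}
    rules = {
        "a": identity_rule("a"),
        "b": identity_rule("b"),
        "c": identity_rule("c"),
        "d": TransferFunction(arity=3, expression=expr),
    }
    return BooleanNetwork(nodes, inputs, rules)


def random_network(spec: RBNSpec) -> BooleanNetwork:
    """Draw an N-K random Boolean network, reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    names = [f"n{i}" for i in range(spec.N)]
    inputs: dict[str, list[str]] = {}
    rules: dict[str, TransferFunction] = {}
    for i, (name, k) in enumerate(zip(names, spec.degrees())):
        pool = list(range(spec.N)) if spec.allow_self_loops else [
            j for j in range(spec.N) if j != i
        ]
        if k > len(pool):
            raise ValueError(f"K={k} exceeds available inputs for node {name}")
        chosen = rng.choice(len(pool), size=k, replace=False)
        ins = [names[pool[j]] for j in sorted(chosen)]
        lut = tuple(int(b) for b in rng.random(2**k) < spec.bias)
        inputs[name] = ins
        rules[name] = TransferFunction(arity=k, lut=lut)
    return BooleanNetwork(names, inputs, rules)


def chain_network(length: int) -> BooleanNetwork:
    """Copy chain x1 -> x2 -> ... -> xL (x1 is an identity self-loop).

    Every node has a single input, so the mean-field activation
    probabilities are exact on this family: there are no correlations
    between inputs to neglect.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    names = [f"x{i}" for i in range(1, length + 1)]
    inputs = {names[0]: [names[0]]}
    rules: dict[str, TransferFunction] = {names[0]: identity_rule(names[0])}
    for prev, cur in zip(names, names[1:]):
        inputs[cur] = [prev]
        rules[cur] = TransferFunction(arity=1, expression=Var(prev), lut=(0, 1))
    return BooleanNetwork(names, inputs, rules)
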