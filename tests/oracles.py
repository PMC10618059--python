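"""Independent brute-force oracles shared by the test modules.

Everything here is deliberately naive (exhaustive enumeration) and
independent of the code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from booldoi.expr import And, Expr, Not, Or, Var, evaluate


def truth_table(expr: Expr, inputs: list[str]) -> tuple[int, ...]:
    """Outputs of ``expr`` on all input tuples in canonical row order."""
    k = len(inputs)
    out = []
    for bits in itertools.product((0, 1), repeat=k):
        out.append(evaluate(expr, dict(zip(inputs, bits))))
    return tuple(out)


def clause_set_truth_table(clauses, inputs: list[str]) -> tuple[int, ...]:
    """Truth table of a DNF clause collection (mappings input -> bit)."""
    k = len(inputs)
    out = []
    for bits in itertools.product((0, 1), repeat=k):
        env = dict(zip(inputs, bits))
        out.append(int(any(all(env[x] == v for x, v in c.items()) for c in clauses)))
    return tuple(out)


def pattern_covers(pattern: str, bits) -> bool:
    return all(s == "#" or int(s) == b for s, b in zip(pattern, bits))


def brute_prime_implicants(lut, output_value: int) -> set[str]:
    """All prime implicants by enumerating every {0,1,#}^k pattern."""
    k = len(lut).bit_length() - 1
    rows = list(itertools.product((0, 1), repeat=k))

    def is_implicant(pattern: str) -> bool:
        covered = [r for r in rows if pattern_covers(pattern, r)]
        return bool(covered) and all(
            lut[int("".join(map(str, r)), 2)] == output_value for r in covered
        )

    implicants = {
        "".join(p) for p in itertools.product("01#", repeat=k) if is_implicant("".join(p))
    }
    primes = set()
    for p in implicants:
        generalizations = [
            p[:i] + "#" + p[i + 1 :] for i in range(k) if p[i] != "#"
        ]
        if not any(g in implicants for g in generalizations):
            primes.add(p)
    if k == 0 and any(b == output_value for b in lut):
        primes.add("")
    return primes


def random_expression(rng: np.random.Generator, names: list[str], depth: int = 3) -> Expr:
    """Random expression tree over ``names`` (all operators reachable)."""
    if depth == 0 or rng.random() < 0.3:
        return Var(names[rng.integers(len(names))])
    op = rng.integers(3)
    if op == 0:
        return Not(random_expression(rng, names, depth - 1))
    args = tuple(
        random_expression(rng, names, depth - 1) for _ in range(rng.integers(2, 4))
    )
    return And(args) if op == 1 else Or(args)


def random_lut(rng: np.random.Generator, k: int, bias: float = 0.5) -> tuple[int, ...]:
    return tuple(int(b) for b in rng.random(2**k) < bias)
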