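"""Transfer-function representations: DNF, prime implicants, schemas.

Three engines for rewriting a Boolean transfer function:

* :func:`to_dnf` — purely syntactic disjunctive normal form (push NOT to
  the literals, distribute AND over OR).  Deliberately *not* minimized:
  the clause set mirrors the expression as given, dropping only
  duplicate clauses and clauses containing a literal and its negation.
* :func:`prime_implicants` — all prime implicants of a complete LUT via
  Quine–McCluskey iterative merging.
* :func:`redescribe` — two-symbol schema redescription: prime implicants
  that are input-permutations of one another are merged into schemas
  with position-free groups ("at least m of these inputs at value v").

All three are checked against the source truth table by exhaustive
expansion (:func:`expand_schema`), which is the module's correctness
contract.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

from .expr import And, Const, Expr, Not, Or, Var
from .network import input_tuple

__all__ = [
    "DNFClauseSet",
    "Implicant",
    "Group",
    "TwoSymbolSchema",
    "DNFBlowupError",
    "to_dnf",
    "prime_implicants",
    "redescribe",
    "expand_schema",
]

#: default guard against combinatorial blow-up during distribution
DEFAULT_MAX_CLAUSES = 2**16


class DNFBlowupError(RuntimeError):
    """Raised when DNF distribution exceeds the intermediate-clause cap."""


Clause = Mapping[str, int]


@dataclass(frozen=True)
class DNFClauseSet:
    """A disjunction of AND-clauses, each a mapping input -> literal value."""

    output_value: int
    clauses: tuple[dict, ...]

    def __len__(self) -> int:
        return len(self.clauses)

    def evaluate(self, env: Mapping[str, int]) -> int:
        return int(
            any(all(env[x] == v for x, v in c.items()) for c in self.clauses)
        )


@dataclass(frozen=True)
class Implicant:
    """A per-input symbol pattern over {0, 1, #} implying a fixed output."""

    pattern: str

    @property
    def arity(self) -> int:
        return len(self.pattern)

    def matches(self, bits: Sequence[int]) -> bool:
        return all(s == "#" or int(s) == b for s, b in zip(self.pattern, bits))

    def literals(self) -> dict[int, int]:
        """Non-wildcard positions and their required bits."""
        return {i: int(s) for i, s in enumerate(self.pattern) if s != "#"}


@dataclass(frozen=True)
class Group:
    """A position-free group: at least ``min_count`` members at ``value``."""

    members: tuple[int, ...]
    value: int
    min_count: int


@dataclass(frozen=True)
class TwoSymbolSchema:
    """Two-symbol redescription: fixed symbols plus position-free groups.

    ``fixed`` assigns a symbol in {0, 1, #} to every non-grouped input
    position; ``groups`` are disjoint from each other and from the fixed
    positions.
    """

    arity: int
    output_value: int
    fixed: tuple[tuple[int, str], ...]
    groups: tuple[Group, ...] = field(default=())

    def fixed_dict(self) -> dict[int, str]:
        return dict(self.fixed)

    def symbol_string(self) -> str:
        """Render with group members shown at their group value."""
        out = ["#"] * self.arity
        for pos, sym in self.fixed:
            out[pos] = sym
        for g in self.groups:
            for m in g.members:
                out[m] = str(g.value)
        return "".join(out)

    def to_dict(self) -> dict:
        return {
            "arity": self.arity,
            "output_value": self.output_value,
            "symbols": "".join(dict(self.fixed).get(i, "#") for i in range(self.arity)),
            "groups": [
                {"members": list(g.members), "value": g.value, "min_count": g.min_count}
                for g in self.groups
            ],
        }


# --------------------------------------------------------------------------
# DNF


def _nnf(expr: Expr, negate: bool) -> Expr:
    """Negation normal form via De Morgan; NOT appears only on variables."""
    if isinstance(expr, Var):
        return Not(expr) if negate else expr
    if isinstance(expr, Const):
        return Const(1 - expr.value) if negate else expr
    if isinstance(expr, Not):
        return _nnf(expr.operand, not negate)
    if isinstance(expr, And):
        args = tuple(_nnf(a, negate) for a in expr.args)
        return Or(args) if negate else And(args)
    if isinstance(expr, Or):
        args = tuple(_nnf(a, negate) for a in expr.args)
        return And(args) if negate else Or(args)
    raise TypeError(f"not an expression: {expr!r}")


def _clause_product(
    sets: Iterable[list[frozenset]], max_clauses: int
) -> list[frozenset]:
    result: list[frozenset] = [frozenset()]
    for clause_set in sets:
        new: list[frozenset] = []
        seen: set[frozenset] = set()
        for left in result:
            for right in clause_set:
                merged = left | right
                if len(new) + 1 > max_clauses:
                    raise DNFBlowupError(
                        f"DNF distribution exceeded {max_clauses} clauses"
                    )
                if merged not in seen:
                    seen.add(merged)
                    new.append(merged)
        result = new
    return result


def _distribute(expr: Expr, max_clauses: int) -> list[frozenset]:
    """DNF of an NNF expression as a list of frozensets of (name, bit)."""
    if isinstance(expr, Var):
        return [frozenset({(expr.name, 1)})]
    if isinstance(expr, Not):
        assert isinstance(expr.operand, Var)
        return [frozenset({(expr.operand.name, 0)})]
    if isinstance(expr, Const):
        return [frozenset()] if expr.value else []
    if isinstance(expr, Or):
        out: list[frozenset] = []
        seen: set[frozenset] = set()
        for a in expr.args:
            for c in _distribute(a, max_clauses):
                if c not in seen:
                    seen.add(c)
                    out.append(c)
                if len(out) > max_clauses:
                    raise DNFBlowupError(
                        f"DNF distribution exceeded {max_clauses} clauses"
                    )
        return out
    if isinstance(expr, And):
        return _clause_product(
            (_distribute(a, max_clauses) for a in expr.args), max_clauses
        )
    raise TypeError(f"not an expression: {expr!r}")


def _clause_sort_key(clause: dict) -> tuple:
    return tuple(sorted(clause.items()))


def to_dnf(
    expression: Expr,
    negate: bool = False,
    max_clauses: int = DEFAULT_MAX_CLAUSES,
) -> DNFClauseSet:
    """Syntactic DNF of an expression (or of its negation).

    The clause set is not reduced beyond dropping duplicate clauses and
    contradictory clauses (a literal and its negation in one clause).
    """
    nnf = _nnf(expression, negate)
    raw = _distribute(nnf, max_clauses)
    clauses = []
    seen: set[frozenset] = set()
    for c in raw:
        by_name: dict[str, int] = {}
        contradictory = False
        for name, bit in sorted(c):
            if by_name.get(name, bit) != bit:
                contradictory = True
                break
            by_name[name] = bit
        if contradictory:
            continue
        key = frozenset(by_name.items())
        if key in seen:
            continue
        seen.add(key)
        clauses.append(by_name)
    clauses.sort(key=_clause_sort_key)
    return DNFClauseSet(output_value=0 if negate else 1, clauses=tuple(clauses))


# --------------------------------------------------------------------------
# Quine-McCluskey prime implicants


def prime_implicants(lut: Sequence[int], output_value: int = 1) -> list[Implicant]:
    """All prime implicants of the LUT rows with the given output.

    Iterative merging of implicants adjacent in one position; an
    implicant is prime when no single-position generalization remains an
    implicant.  The union of the expansions equals exactly the matching
    rows.
    """
    n_rows = len(lut)
    k = n_rows.bit_length() - 1
    if 2**k != n_rows:
        raise ValueError("LUT length must be a power of two")
    minterms = [r for r in range(n_rows) if lut[r] == output_value]
    if not minterms:
        return []
    if k == 0:
        return [Implicant("")]

    # (bits, mask): mask bit 1 = fixed position, 0 = wildcard; MSB = input 0.
    current = {(r, (1 << k) - 1) for r in minterms}
    primes: set[tuple[int, int]] = set()
    while current:
        merged_away: set[tuple[int, int]] = set()
        nxt: set[tuple[int, int]] = set()
        cur = list(current)
        by_mask: dict[int, list[int]] = {}
        for bits, mask in cur:
            by_mask.setdefault(mask, []).append(bits)
        for mask, group in by_mask.items():
            group_set = set(group)
            for bits in group:
                for pos in range(k):
                    bit = 1 << (k - 1 - pos)
                    if not mask & bit:
                        continue
                    partner = bits ^ bit
                    if partner in group_set:
                        nxt.add((bits & ~bit, mask & ~bit))
                        merged_away.add((bits, mask))
                        merged_away.add((partner, mask))
        primes |= current - merged_away
        current = nxt

    def to_pattern(bits: int, mask: int) -> str:
        out = []
        for pos in range(k):
            bit = 1 << (k - 1 - pos)
            if mask & bit:
                out.append("1" if bits & bit else "0")
            else:
                out.append("#")
        return "".join(out)

    patterns = sorted(to_pattern(b, m) for b, m in primes)
    return [Implicant(p) for p in patterns]


# --------------------------------------------------------------------------
# Two-symbol schema redescription


def _transposed_pair(p: str, q: str) -> tuple[int, int] | None:
    """Positions (i, j) if q is p with exactly two symbols swapped."""
    diff = [i for i in range(len(p)) if p[i] != q[i]]
    if len(diff) == 2 and p[diff[0]] == q[diff[1]] and p[diff[1]] == q[diff[0]]:
        return diff[0], diff[1]
    return None


def _merge_cluster(
    patterns: list[str], swaps: list[tuple[int, int]], output_value: int
) -> TwoSymbolSchema | None:
    """Try to merge a transposition-connected cluster into one schema."""
    k = len(patterns[0])
    fixed_pos = [i for i in range(k) if len({p[i] for p in patterns}) == 1]
    varying = [i for i in range(k) if i not in fixed_pos]

    # Blocks: connected components of varying positions under the swaps.
    parent = {i: i for i in varying}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in swaps:
        if a in parent and b in parent:
            parent[find(a)] = find(b)
    blocks: dict[int, list[int]] = {}
    for i in varying:
        blocks.setdefault(find(i), []).append(i)

    groups = []
    for members in blocks.values():
        multisets = {tuple(sorted(p[i] for i in members)) for p in patterns}
        if len(multisets) != 1:
            return None
        ms = multisets.pop()
        symbols = set(ms)
        if not (symbols <= {"0", "#"} or symbols <= {"1", "#"}) or symbols == {"#"}:
            return None
        value = 0 if "0" in symbols else 1
        m = sum(1 for s in ms if s != "#")
        groups.append(Group(tuple(sorted(members)), value, m))

    # Closure check: the cluster must contain every arrangement.
    expected = 1
    for g in groups:
        expected *= comb(len(g.members), g.min_count)
    if expected != len(patterns):
        return None
    base = {i: patterns[0][i] for i in fixed_pos}
    generated = set()
    per_block = []
    for g in groups:
        arrangements = []
        for chosen in itertools.combinations(g.members, g.min_count):
            arrangements.append({i: str(g.value) if i in chosen else "#" for i in g.members})
        per_block.append(arrangements)
    for combo in itertools.product(*per_block):
        symbols = dict(base)
        for assignment in combo:
            symbols.update(assignment)
        generated.add("".join(symbols[i] for i in range(k)))
    if generated != set(patterns):
        return None
    return TwoSymbolSchema(
        arity=k,
        output_value=output_value,
        fixed=tuple(sorted((i, patterns[0][i]) for i in fixed_pos)),
        groups=tuple(sorted(groups, key=lambda g: g.members)),
    )


def _schema_sort_key(s: TwoSymbolSchema) -> tuple:
    return (s.symbol_string(), tuple((g.members, g.value, g.min_count) for g in s.groups))


def redescribe(lut: Sequence[int], output_value: int = 1) -> list[TwoSymbolSchema]:
    """Two-symbol schema redescription of a complete LUT.

    Prime implicants sharing a symbol multiset are clustered by
    transposition adjacency; a cluster whose members are exactly the
    arrangements of "at least m at value v" groups collapses to a single
    schema.  Clusters with more exotic permutation structure fall back
    to ungrouped (fixed-only) schemas, preserving the expansion
    contract.
    """
    pis = prime_implicants(lut, output_value)
    k = pis[0].arity if pis else (len(lut).bit_length() - 1)
    by_multiset: dict[tuple, list[str]] = {}
    for imp in pis:
        by_multiset.setdefault(tuple(sorted(imp.pattern)), []).append(imp.pattern)

    schemas: list[TwoSymbolSchema] = []
    for patterns in by_multiset.values():
        # Transposition-connected clusters of implicants.
        idx = {p: i for i, p in enumerate(patterns)}
        parent = list(range(len(patterns)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for p, q in itertools.combinations(patterns, 2):
            swap = _transposed_pair(p, q)
            if swap is not None:
                ri, rj = find(idx[p]), find(idx[q])
                parent[ri] = rj
        clusters: dict[int, list[str]] = {}
        for p in patterns:
            clusters.setdefault(find(idx[p]), []).append(p)
        for members in clusters.values():
            swaps = [
                s
                for p, q in itertools.combinations(members, 2)
                if (s := _transposed_pair(p, q)) is not None
            ]
            merged = None
            if len(members) > 1:
                merged = _merge_cluster(sorted(members), swaps, output_value)
            if merged is not None:
                schemas.append(merged)
            else:
                for p in sorted(members):
                    schemas.append(
                        TwoSymbolSchema(
                            arity=k,
                            output_value=output_value,
                            fixed=tuple((i, s) for i, s in enumerate(p)),
                            groups=(),
                        )
                    )
    schemas.sort(key=_schema_sort_key)
    return schemas


# --------------------------------------------------------------------------
# Expansion oracle


def expand_schema(
    schema: TwoSymbolSchema | Implicant, arity: int | None = None
) -> set[tuple[int, ...]]:
    """Every concrete input tuple covered by an implicant or schema.

    Wildcards range over {0, 1}; each group contributes all assignments
    of its members with at least ``min_count`` members at the group's
    value.
    """
    if isinstance(schema, Implicant):
        k = schema.arity if arity is None else arity
        options = [
            ((0, 1) if s == "#" else (int(s),)) for s in schema.pattern.ljust(k, "#")
        ]
        return set(itertools.product(*options))
    k = schema.arity if arity is None else arity
    fixed = schema.fixed_dict()
    options = []
    for i in range(k):
        s = fixed.get(i, "#")
        options.append((0, 1) if s == "#" else (int(s),))
    out = set()
    for bits in itertools.product(*options):
        ok = True
        for g in schema.groups:
            if sum(1 for m in g.members if bits[m] == g.value) < g.min_count:
                ok = False
                break
        if ok:
            out.add(bits)
    return out


def matching_rows(lut: Sequence[int], output_value: int) -> set[tuple[int, ...]]:
    """Input tuples of the LUT rows carrying ``output_value`` (oracle helper)."""
    k = len(lut).bit_length() - 1
    return {input_tuple(r, k) for r in range(len(lut)) if lut[r] == output_value}
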