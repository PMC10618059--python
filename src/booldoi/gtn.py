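"""Generalized threshold networks (GTNs).

A GTN is a static directed graph that encodes the full transition logic
of a Boolean network.  It contains ``2N`` *state nodes* (one per node
and per binary value, labelled ``i-0`` / ``i-1``) plus *threshold
nodes*: integer-threshold gates that fire when at least ``tau`` of their
inputs are satisfied.  Three builders are provided, one per
transfer-function representation:

``LUT``
    One threshold node per look-up-table row (threshold = arity).
``DNF``
    One threshold node per disjunctive clause (threshold = clause
    length), for both the expression and its negation.  Nodes lacking an
    expression fall back to Quine-McCluskey prime implicants.
``SR``
    Per two-symbol schema, one *group* threshold node per position-free
    group (threshold = the group's minimum count) feeding a *final*
    threshold node together with the fixed literals.

State transitions are unambiguous in all three: for any complete input
assignment exactly one of ``i-0`` / ``i-1`` is derivable, and it equals
the transfer function (see :func:`verify_gtn`).

Graph nodes are keyed ``("state", var, value)`` and ``("thr", id)``;
threshold ids are deterministic strings ``"node|value|index"`` (group
nodes append ``"|g<j>"``) so exports are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .logic import prime_implicants, redescribe, to_dnf, DEFAULT_MAX_CLAUSES
from .network import BooleanNetwork, input_tuple

__all__ = [
    "GTN",
    "build_gtn",
    "size_bounds",
    "transfer_subgraph",
    "verify_gtn",
    "export_gtn",
    "import_gtn",
]

REPRESENTATIONS = ("LUT", "DNF", "SR")


def state_key(var: str, value: int) -> tuple:
    return ("state", var, int(value))


def thr_key(tid: str) -> tuple:
    return ("thr", tid)


def state_label(var: str, value: int) -> str:
    return f"{var}-{value}"


@dataclass
class GTN:
    """A generalized threshold network over a Boolean network."""

    graph: nx.DiGraph
    representation: str
    network: BooleanNetwork | None = field(default=None, repr=False)

    @property
    def state_nodes(self) -> list[tuple]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "state"]

    @property
    def threshold_nodes(self) -> list[tuple]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "thr"]

    @property
    def M(self) -> int:
        """Number of threshold nodes."""
        return len(self.threshold_nodes)

    @property
    def E(self) -> int:
        """Number of directed edges."""
        return self.graph.number_of_edges()

    def has_state(self, var: str, value: int) -> bool:
        return state_key(var, value) in self.graph

    def tau(self, node: tuple) -> int:
        return self.graph.nodes[node]["tau"]


def _add_state_nodes(g: nx.DiGraph, net: BooleanNetwork) -> None:
    for n in net.nodes:
        for v in (0, 1):
            g.add_node(state_key(n, v), kind="state", var=n, value=v)


def _add_clause(
    g: nx.DiGraph,
    tid: str,
    literals: Iterable[tuple[str, int]],
    target: tuple,
) -> None:
    lits = list(literals)
    node = thr_key(tid)
    g.add_node(node, kind="thr", tau=len(lits), layer="final")
    for var, bit in lits:
        g.add_edge(state_key(var, bit), node)
    g.add_edge(node, target)


def build_gtn(
    net: BooleanNetwork,
    representation: str = "DNF",
    qm_fallback: bool = True,
    input_logic: bool = True,
    max_clauses: int = DEFAULT_MAX_CLAUSES,
) -> GTN:
    """Build the GTN of ``net`` under one of the LUT/DNF/SR representations.

    Both output polarities are always built (the inhibition logic of
    ``i-0`` is required for negative inference).  ``qm_fallback``
    controls whether the DNF builder may derive clauses from prime
    implicants when a node has no expression; ``input_logic=False``
    omits the identity self-loop logic of environmental input nodes
    (pure-source semantics).
    """
    if representation not in REPRESENTATIONS:
        raise ValueError(f"unknown representation {representation!r}")
    g = nx.DiGraph()
    _add_state_nodes(g, net)
    for i in net.nodes:
        if not input_logic and net.is_identity_input(i):
            continue
        ins = net.inputs[i]
        k = len(ins)
        for v in (0, 1):
            target = state_key(i, v)
            if representation == "LUT":
                lut = net.lut(i)
                idx = 0
                for r in range(2**k):
                    if lut[r] != v:
                        continue
                    bits = input_tuple(r, k)
                    _add_clause(
                        g, f"{i}|{v}|{idx}", zip(ins, bits), target
                    )
                    idx += 1
            elif representation == "DNF":
                tf = net.rules[i]
                if tf.expression is not None:
                    clause_set = to_dnf(
                        tf.expression, negate=(v == 0), max_clauses=max_clauses
                    )
                    clauses = [list(c.items()) for c in clause_set.clauses]
                else:
                    if not qm_fallback:
                        raise ValueError(
                            f"node {i!r} has no expression and QM fallback is off"
                        )
                    clauses = [
                        [(ins[p], b) for p, b in imp.literals().items()]
                        for imp in prime_implicants(net.lut(i), v)
                    ]
                for idx, clause in enumerate(clauses):
                    _add_clause(g, f"{i}|{v}|{idx}", clause, target)
            else:  # SR
                for idx, schema in enumerate(redescribe(net.lut(i), v)):
                    group_nodes = []
                    for gi, grp in enumerate(schema.groups):
                        gnode = thr_key(f"{i}|{v}|{idx}|g{gi}")
                        g.add_node(gnode, kind="thr", tau=grp.min_count, layer="group")
                        for m in grp.members:
                            g.add_edge(state_key(ins[m], grp.value), gnode)
                        group_nodes.append(gnode)
                    fixed_lits = [
                        (ins[p], int(s)) for p, s in schema.fixed if s != "#"
                    ]
                    fnode = thr_key(f"{i}|{v}|{idx}")
                    g.add_node(
                        fnode,
                        kind="thr",
                        tau=len(fixed_lits) + len(group_nodes),
                        layer="final",
                    )
                    for var, bit in fixed_lits:
                        g.add_edge(state_key(var, bit), fnode)
                    for gnode in group_nodes:
                        g.add_edge(gnode, fnode)
                    g.add_edge(fnode, target)
    return GTN(graph=g, representation=representation, network=net)


def size_bounds(net: BooleanNetwork) -> tuple[int, int]:
    """Upper bounds (M, E) on threshold-node and edge counts of any GTN.

    The LUT builder attains both bounds with equality: node ``i`` with
    ``k_i`` inputs contributes ``2**k_i`` threshold nodes and
    ``(k_i + 1) * 2**k_i`` edges (``k_i`` in-edges per row plus the edge
    into the state node).  Identity self-loops contribute ``k = 1``
    terms.
    """
    M = sum(2 ** net.degree(i) for i in net.nodes)
    E = sum((net.degree(i) + 1) * 2 ** net.degree(i) for i in net.nodes)
    return M, E


def transfer_subgraph(gtn: GTN, node: str, value: int) -> nx.DiGraph:
    """The portion of the GTN concerning one state transition.

    Returns the subgraph induced by the state node ``node-value``, all
    threshold nodes whose threshold-node path terminates at it, and the
    state nodes feeding those threshold nodes — with exactly the edges
    traversed by that reverse reachability.
    """
    target = state_key(node, value)
    if target not in gtn.graph:
        raise KeyError(f"unknown state node {node!r}-{value}")
    sub = nx.DiGraph()
    sub.add_node(target, **gtn.graph.nodes[target])
    stack = [p for p in gtn.graph.predecessors(target)]
    edges = [(p, target) for p in stack]
    seen = set(stack)
    while stack:
        t = stack.pop()
        if gtn.graph.nodes[t]["kind"] != "thr":
            continue
        sub.add_node(t, **gtn.graph.nodes[t])
        for p in gtn.graph.predecessors(t):
            edges.append((p, t))
            if p not in seen:
                seen.add(p)
                if gtn.graph.nodes[p]["kind"] == "thr":
                    stack.append(p)
                else:
                    sub.add_node(p, **gtn.graph.nodes[p])
    sub.add_edges_from(edges)
    return sub


# --------------------------------------------------------------------------
# Logical-completeness verification


def verify_gtn(gtn: GTN, max_arity: int = 8) -> None:
    """Check that the GTN's logic matches every transfer function.

    For each node ``i`` and each of the ``2**k_i`` input assignments,
    exactly one of ``i-0`` / ``i-1`` must be derivable from the fired
    thresholds, and it must equal ``F_i`` of that assignment.  Raises
    ``AssertionError`` on any violation.  Nodes with arity above
    ``max_arity`` are skipped.
    """
    net = gtn.network
    if net is None:
        raise ValueError("GTN carries no network reference")
    for i in net.nodes:
        ins = net.inputs[i]
        k = len(ins)
        if k > max_arity:
            continue
        lut = net.lut(i)
        for r in range(2**k):
            env = dict(zip(ins, input_tuple(r, k)))
            derived = [v for v in (0, 1) if _derivable(gtn, i, v, env)]
            expected = lut[r]
            assert derived == [expected], (
                f"node {i!r}, assignment {env}: derivable {derived}, "
                f"expected [{expected}]"
            )


def _derivable(gtn: GTN, node: str, value: int, env: dict[str, int]) -> bool:
    cone = transfer_subgraph(gtn, node, value)
    target = state_key(node, value)
    # The target may feed its own logic (self-loops), so it is not excluded.
    satisfied = {
        n
        for n, d in cone.nodes(data=True)
        if d["kind"] == "state" and env.get(d["var"]) == d["value"]
    }
    thrs = [n for n, d in cone.nodes(data=True) if d["kind"] == "thr"]
    fired: set = set()
    changed = True
    while changed:
        changed = False
        for t in thrs:
            if t in fired:
                continue
            count = sum(1 for p in cone.predecessors(t) if p in satisfied or p in fired)
            if count >= cone.nodes[t]["tau"]:
                fired.add(t)
                changed = True
    return any(t in fired for t in cone.predecessors(target))


# --------------------------------------------------------------------------
# Serialization


def _thr_label(tid: str, tau: int) -> str:
    return f"T{tid}({tau})"


def _node_label(g: nx.DiGraph, n: tuple) -> str:
    d = g.nodes[n]
    if d["kind"] == "state":
        return state_label(d["var"], d["value"])
    return _thr_label(n[1], d["tau"])


def export_gtn(gtn: GTN, format: str = "json") -> str:
    """Serialize a GTN to JSON or a TSV edge list.

    State labels are ``i-0`` / ``i-1`` and threshold labels
    ``T<id>(tau)``; lossless round-trips via :func:`import_gtn` require
    variable names without ``-``.
    """
    g = gtn.graph
    if format == "json":
        doc = {
            "representation": gtn.representation,
            "state_nodes": [
                {"var": d["var"], "value": d["value"]}
                for n, d in sorted(g.nodes(data=True))
                if d["kind"] == "state"
            ],
            "threshold_nodes": [
                {"id": n[1], "tau": d["tau"], "layer": d["layer"]}
                for n, d in sorted(g.nodes(data=True))
                if d["kind"] == "thr"
            ],
            "edges": [
                [_node_label(g, u), _node_label(g, v)] for u, v in sorted(g.edges())
            ],
        }
        return json.dumps(doc, indent=1)
    if format == "edge_list":
        lines = [f"# representation: {gtn.representation}"]
        for u, v in sorted(g.edges()):
            lines.append(f"{_node_label(g, u)}\t{_node_label(g, v)}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")


def _parse_label(label: str) -> tuple:
    if label.startswith("T") and label.endswith(")") and "(" in label:
        tid, tau = label[1:-1].rsplit("(", 1)
        return thr_key(tid), int(tau)
    var, value = label.rsplit("-", 1)
    return state_key(var, int(value)), None


def import_gtn(text: str, format: str = "json") -> GTN:
    """Inverse of :func:`export_gtn` (network reference is not restored)."""
    g = nx.DiGraph()
    if format == "json":
        doc = json.loads(text)
        for s in doc["state_nodes"]:
            g.add_node(state_key(s["var"], s["value"]), kind="state",
                       var=s["var"], value=s["value"])
        for t in doc["threshold_nodes"]:
            g.add_node(thr_key(t["id"]), kind="thr", tau=t["tau"], layer=t["layer"])
        for src, dst in doc["edges"]:
            g.add_edge(_parse_label(src)[0], _parse_label(dst)[0])
        return GTN(graph=g, representation=doc["representation"])
    if format == "edge_list":
        representation = "DNF"
        edges = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "representation:" in line:
                    representation = line.split(":", 1)[1].strip()
                continue
            src, dst = line.split("\t")
            edges.append((_parse_label(src), _parse_label(dst)))
        for (node, tau) in [e for pair in edges for e in pair]:
            if node not in g:
                if node[0] == "thr":
                    g.add_node(node, kind="thr", tau=tau, layer="final")
                else:
                    g.add_node(node, kind="state", var=node[1], value=node[2])
        for (u, _), (v, _) in edges:
            g.add_edge(u, v)
        # A threshold node feeding another threshold node is a group layer.
        for n, d in g.nodes(data=True):
            if d["kind"] == "thr":
                succs = list(g.successors(n))
                if succs and all(g.nodes[s]["kind"] == "thr" for s in succs):
                    d["layer"] = "group"
        return GTN(graph=g, representation=representation)
    raise ValueError(f"unknown format {format!r}")
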