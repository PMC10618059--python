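"""Estimators of the domain of influence of a pinned seed set.

Pinning a *seed set* ``X`` — a contradiction-free set of (node, value)
pairs held fixed for all time — may drive other nodes to deterministic
long-term states.  The set of all such (node, state) pairs is the
*domain of influence* ``D(X)``.  Three estimators are provided:

* :func:`ground_truth` — the definition itself: average the state at
  time ``T`` over initial configurations of the unpinned nodes, either
  exhaustively (all ``2**(N - |X|)``) or by uniform sampling of ``R``
  configurations; a node belongs to ``D`` iff its mean lands exactly on
  0 or 1.
* :func:`ibmfa_run` / :func:`ibmfa_doi` — the individual-based
  mean-field approximation: iterate per-node activation probabilities
  ``s_i(t)`` assuming independent inputs, starting from 1/2 for
  unpinned nodes; a node is in the domain when ``s_i(T)`` reaches 0 or
  1 (within a tolerance guarding floating-point rounding only).
* :func:`doi_bfs` — exact logical inference on a generalized threshold
  network: a two-queue breadth-first search from the seed state nodes
  that fires threshold nodes immediately within a stage and admits
  state nodes stage by stage, skipping any state node that contradicts
  one already derived.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from collections import deque
from typing import Iterable

import numpy as np

from .gtn import GTN, state_key
from .network import BooleanNetwork

__all__ = [
    "SeedSet",
    "DomainOfInfluence",
    "ActivationTrajectory",
    "doi_bfs",
    "ibmfa_run",
    "ibmfa_doi",
    "ground_truth",
    "mean_trajectory",
]

logger = logging.getLogger(__name__)

#: default horizon considered representative of long-term dynamics
DEFAULT_T = 10
#: default number of sampled initial configurations
DEFAULT_R = 100
#: IBMFA determinism tolerance (guards accumulated rounding only)
DEFAULT_TOL = 1e-9


@dataclass(frozen=True)
class SeedSet:
    """A contradiction-free set of pinned (node, value) pairs."""

    pins: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pins", frozenset((str(i), int(v)) for i, v in self.pins)
        )
        by_node: dict[str, int] = {}
        for i, v in self.pins:
            if by_node.get(i, v) != v:
                raise ValueError(f"seed set pins node {i!r} to both values")
            by_node[i] = v

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "SeedSet":
        return cls(frozenset(pairs))

    @classmethod
    def from_string(cls, text: str) -> "SeedSet":
        """Parse the ``"a=1,c=1"`` command-line syntax."""
        pairs = []
        if text.strip():
            for part in text.split(","):
                name, _, value = part.partition("=")
                if value.strip() not in ("0", "1"):
                    raise ValueError(f"invalid seed specification {part!r}")
                pairs.append((name.strip(), int(value)))
        return cls.from_pairs(pairs)

    def as_dict(self) -> dict[str, int]:
        return {i: v for i, v in self.pins}

    def nodes(self) -> set[str]:
        return {i for i, _ in self.pins}

    def __iter__(self):
        return iter(sorted(self.pins))

    def __len__(self) -> int:
        return len(self.pins)

    def __str__(self) -> str:
        return ",".join(f"{i}={v}" for i, v in sorted(self.pins))


@dataclass
class DomainOfInfluence:
    """A set of (node, state) pairs with provenance.

    ``method`` is one of ``GT``/``IBMFA``/``LUT``/``DNF``/``SR``;
    ``levels`` (BFS methods) records the search stage at which each
    member entered; ``values`` (IBMFA) the converged probabilities.
    """

    members: frozenset
    method: str
    params: dict = field(default_factory=dict)
    levels: dict | None = None
    values: dict | None = None

    def __post_init__(self) -> None:
        self.members = frozenset((str(i), int(v)) for i, v in self.members)
        by_node: dict[str, int] = {}
        for i, v in self.members:
            if by_node.get(i, v) != v:
                raise ValueError(f"domain contains both states of node {i!r}")
            by_node[i] = v

    def __contains__(self, pair) -> bool:
        return (str(pair[0]), int(pair[1])) in self.members

    def __len__(self) -> int:
        return len(self.members)

    def nodes(self) -> set[str]:
        return {i for i, _ in self.members}

    def as_dict(self) -> dict[str, int]:
        return {i: v for i, v in self.members}

    def to_dict(self) -> dict:
        members = [
            {"node": i, "state": v} for i, v in sorted(self.members)
        ]
        if self.levels is not None:
            for m in members:
                m["level"] = self.levels[(m["node"], m["state"])]
        return {"method": self.method, "params": self.params, "members": members}


@dataclass
class ActivationTrajectory:
    """Mean-field activation probabilities ``s_i(t)``, t = 0..T."""

    nodes: list[str]
    values: np.ndarray  # shape (T + 1, N)

    def s(self, node: str, t: int) -> float:
        return float(self.values[t, self.nodes.index(node)])

    @property
    def T(self) -> int:
        return self.values.shape[0] - 1


# --------------------------------------------------------------------------
# BFS on a GTN


def doi_bfs(gtn: GTN, X: SeedSet) -> DomainOfInfluence:
    """Domain of influence by breadth-first search on a GTN.

    Two queues are maintained: threshold nodes whose threshold is met by
    satisfied predecessors (state nodes or fired group thresholds) in
    the visited set are dealt with immediately within the current stage,
    while newly implied state nodes wait for the next stage, so that
    state nodes advance in discrete BFS levels.  State nodes
    contradicting an already-derived state are skipped.
    """
    g = gtn.graph
    Q: deque = deque()
    for i, v in sorted(X.pins):
        key = state_key(i, v)
        if key not in g:
            raise KeyError(f"seed node {i!r} absent from GTN")
        Q.append(key)
    S: set = set()
    queued: set = set(Q)
    derived: dict[str, int] = {}
    levels: dict[tuple[str, int], int] = {}
    r = 0
    next_q: deque = deque()
    while Q:
        while Q:
            e = Q.popleft()
            if e in S:
                continue
            if e[0] == "state":
                var, val = e[1], e[2]
                if derived.get(var, val) != val:
                    logger.debug("skipping contradicting state node %s-%s", var, val)
                    continue
                derived[var] = val
                levels[(var, val)] = r
            S.add(e)
            for n in g.successors(e):
                if n in S or n in queued:
                    continue
                if n[0] == "thr":
                    tau = g.nodes[n]["tau"]
                    met = sum(1 for p in g.predecessors(n) if p in S)
                    if met >= tau:
                        Q.append(n)
                        queued.add(n)
                else:
                    var, val = n[1], n[2]
                    if derived.get(var, val) != val:
                        logger.debug(
                            "not queueing contradicting state node %s-%s", var, val
                        )
                        continue
                    next_q.append(n)
                    queued.add(n)
        if next_q:
            r += 1
            Q, next_q = next_q, deque()
    return DomainOfInfluence(
        members=frozenset(derived.items()),
        method=gtn.representation,
        params={"seeds": str(X)},
        levels=levels,
    )


# --------------------------------------------------------------------------
# Individual-based mean-field approximation


def ibmfa_run(net: BooleanNetwork, X: SeedSet, T: int = DEFAULT_T) -> ActivationTrajectory:
    """Iterate the mean-field activation probabilities for ``T`` steps.

    ``s_i(0) = 1/2`` off-seed and the pinned value on-seed; thereafter
    each unpinned node sums, over the ``2**k_i`` input assignments with
    output 1, the product of its inputs' (in)activation probabilities —
    inputs are treated as independent, which is exact only when no
    correlations develop (e.g. on trees).  Cost per step is
    ``O(sum_i 2**k_i)``.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    pins = X.as_dict()
    unknown = set(pins) - set(net.nodes)
    if unknown:
        raise KeyError(f"seed nodes not in network: {sorted(unknown)}")
    index = {n: i for i, n in enumerate(net.nodes)}
    N = net.N
    # Per-node row bit matrices (2^k, k) in canonical row order.
    bit_rows = []
    luts = []
    in_idx = []
    for n in net.nodes:
        k = net.degree(n)
        rows = np.arange(2**k)
        shifts = np.arange(k - 1, -1, -1)
        bit_rows.append(((rows[:, None] >> shifts[None, :]) & 1).astype(float))
        luts.append(np.array(net.lut(n), dtype=float))
        in_idx.append(np.array([index[j] for j in net.inputs[n]], dtype=np.intp))

    s = np.full(N, 0.5)
    for i, v in pins.items():
        s[index[i]] = v
    values = np.empty((T + 1, N))
    values[0] = s
    pinned_idx = np.array([index[i] for i in pins], dtype=np.intp)
    for t in range(1, T + 1):
        new = np.empty(N)
        for i in range(N):
            B = bit_rows[i]
            if B.shape[1] == 0:
                new[i] = luts[i][0]
                continue
            p = s[in_idx[i]]
            probs = np.prod(B * p[None, :] + (1.0 - B) * (1.0 - p[None, :]), axis=1)
            new[i] = probs @ luts[i]
        if pinned_idx.size:
            new[pinned_idx] = values[0][pinned_idx]
        s = new
        values[t] = s
    return ActivationTrajectory(nodes=list(net.nodes), values=values)


def ibmfa_doi(
    net: BooleanNetwork,
    X: SeedSet,
    T: int = DEFAULT_T,
    tolerance: float = DEFAULT_TOL,
) -> DomainOfInfluence:
    """Mean-field domain of influence: nodes with ``s_i(T)`` at 0 or 1."""
    traj = ibmfa_run(net, X, T)
    s = traj.values[-1]
    members = []
    values = {}
    for i, n in enumerate(net.nodes):
        if s[i] <= tolerance:
            members.append((n, 0))
            values[n] = float(s[i])
        elif s[i] >= 1.0 - tolerance:
            members.append((n, 1))
            values[n] = float(s[i])
    return DomainOfInfluence(
        members=frozenset(members),
        method="IBMFA",
        params={"seeds": str(X), "T": T, "tolerance": tolerance},
        values=values,
    )


# --------------------------------------------------------------------------
# Ground truth


def _initial_states(
    net: BooleanNetwork,
    X: SeedSet,
    mode: str,
    R: int,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, str, int]:
    pins = X.as_dict()
    unknown = set(pins) - set(net.nodes)
    if unknown:
        raise KeyError(f"seed nodes not in network: {sorted(unknown)}")
    index = {n: i for i, n in enumerate(net.nodes)}
    free = [n for n in net.nodes if n not in pins]
    n_free = len(free)
    if mode == "auto":
        mode = "brute" if n_free <= 10 else "sample"
    if mode == "brute":
        R = 2**n_free
        ints = np.arange(R, dtype=np.int64)
        shifts = np.arange(n_free - 1, -1, -1, dtype=np.int64)
        bits = ((ints[:, None] >> shifts[None, :]) & 1).astype(np.uint8)
    elif mode == "sample":
        if R < 1:
            raise ValueError("R must be >= 1")
        if R > 2**n_free:
            warnings.warn(
                f"sampling {R} configurations with replacement from a state "
                f"space of {2 ** n_free}",
                stacklevel=3,
            )
        rng = np.random.default_rng(rng)
        bits = rng.integers(0, 2, size=(R, n_free), dtype=np.uint8)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    states = np.empty((R, net.N), dtype=np.uint8)
    for j, n in enumerate(free):
        states[:, index[n]] = bits[:, j]
    for n, v in pins.items():
        states[:, index[n]] = v
    return states, mode, R


def mean_trajectory(
    net: BooleanNetwork,
    X: SeedSet,
    T: int = DEFAULT_T,
    R: int = DEFAULT_R,
    mode: str = "auto",
    rng: np.random.Generator | int | None = None,
) -> tuple[list[str], np.ndarray]:
    """Ensemble-mean state per node at every t = 0..T.

    Returns ``(nodes, means)`` with ``means`` of shape ``(T + 1, N)``;
    the average runs over all (brute) or ``R`` sampled initial
    configurations of the unpinned nodes, with the seed set pinned.
    """
    states, _, R_used = _initial_states(net, X, mode, R, rng)
    compiled = net.compiled()
    index = compiled.index
    pins = X.as_dict()
    pin_idx = np.array([index[i] for i in pins], dtype=np.intp)
    pin_val = np.array([pins[net.nodes[i]] for i in pin_idx], dtype=np.uint8)
    means = np.empty((T + 1, net.N))
    means[0] = states.mean(axis=0)
    for t in range(1, T + 1):
        states = compiled.step_ensemble(states)
        if pin_idx.size:
            states[:, pin_idx] = pin_val[None, :]
        means[t] = states.mean(axis=0)
    return list(net.nodes), means


def ground_truth(
    net: BooleanNetwork,
    X: SeedSet,
    T: int = DEFAULT_T,
    R: int = DEFAULT_R,
    mode: str = "auto",
    rng: np.random.Generator | int | None = None,
    window: int = 0,
) -> tuple[dict[str, float], DomainOfInfluence]:
    """Ground-truth mean states and domain of influence.

    ``mode="auto"`` enumerates all initial configurations when the free
    state space has at most ``2**10`` of them, otherwise samples ``R``
    i.i.d. uniform initializations (with replacement).  A node joins
    ``D(X)`` iff every realization agrees at time ``T`` — exactly, via
    integer counts, not a float comparison.  ``window > 0`` additionally
    requires constancy over ``[T, T + window]`` (strict mode; the
    default follows the single-time definition).
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    states, mode_used, R_used = _initial_states(net, X, mode, R, rng)
    compiled = net.compiled()
    index = compiled.index
    pins = X.as_dict()
    pin_idx = np.array([index[i] for i in pins], dtype=np.intp)
    pin_val = np.array([pins[net.nodes[i]] for i in pin_idx], dtype=np.uint8)
    for _ in range(T):
        states = compiled.step_ensemble(states)
        if pin_idx.size:
            states[:, pin_idx] = pin_val[None, :]
    counts = states.sum(axis=0, dtype=np.int64)
    constant = (counts == 0) | (counts == R_used)
    if window > 0:
        value_at_T = states.copy()
        for _ in range(window):
            states = compiled.step_ensemble(states)
            if pin_idx.size:
                states[:, pin_idx] = pin_val[None, :]
            constant &= (states == value_at_T).all(axis=0)
    means = {n: float(counts[i]) / R_used for i, n in enumerate(net.nodes)}
    members = [
        (n, int(counts[i] // R_used))
        for i, n in enumerate(net.nodes)
        if constant[i]
    ]
    params: dict = {"seeds": str(X), "T": T, "mode": mode_used, "R": R_used}
    if window:
        params["window"] = window
    return means, DomainOfInfluence(
        members=frozenset(members), method="GT", params=params
    )
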