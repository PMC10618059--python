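"""Metrics, seed-set enumeration and the benchmark harness.

Approximate domains of influence are compared against the ground truth
over the universe of all ``2N`` (node, state) pairs: true/false
positives and negatives, precision, recall and the Jaccard index, plus
Spearman rank correlation between predicted and true domain sizes
across seed sets.  The benchmark runner builds each requested GTN once
(amortizing the build time over seed sets) and the sub-sampling
experiment quantifies how estimating the ground truth from a fraction
``p`` of the initial-configuration space inflates the domain.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gtn import build_gtn
from .influence import (
    DEFAULT_R,
    DEFAULT_T,
    DEFAULT_TOL,
    DomainOfInfluence,
    SeedSet,
    doi_bfs,
    ground_truth,
    ibmfa_doi,
)
from .network import BooleanNetwork

__all__ = [
    "ConfusionSets",
    "BenchmarkReport",
    "confusion",
    "precision_recall",
    "jaccard",
    "spearman_rho",
    "seed_sets",
    "pair_universe",
    "run_benchmark",
    "subsample_experiment",
]

GTN_METHODS = ("LUT", "DNF", "SR")
ALL_METHODS = GTN_METHODS + ("IBMFA",)


@dataclass(frozen=True)
class ConfusionSets:
    """Partition of the 2N pair universe induced by truth D and estimate DZ."""

    tp: frozenset
    tn: frozenset
    fp: frozenset
    fn: frozenset


def pair_universe(net: BooleanNetwork) -> frozenset:
    return frozenset((n, v) for n in net.nodes for v in (0, 1))


def confusion(
    D: DomainOfInfluence | Iterable,
    DZ: DomainOfInfluence | Iterable,
    universe: Iterable,
) -> ConfusionSets:
    """Set algebra of true/false positives and negatives over ``universe``."""
    d = frozenset(D.members if isinstance(D, DomainOfInfluence) else D)
    dz = frozenset(DZ.members if isinstance(DZ, DomainOfInfluence) else DZ)
    u = frozenset(universe)
    if not d <= u or not dz <= u:
        raise ValueError("domains contain pairs outside the universe")
    return ConfusionSets(
        tp=d & dz,
        tn=u - d - dz,
        fp=dz - d,
        fn=d - dz,
    )


def precision_recall(cs: ConfusionSets) -> tuple[float, float]:
    """Precision |TP|/(|TP|+|FP|) and recall |TP|/(|TP|+|FN|).

    An empty prediction has precision 1.0 and an empty truth has recall
    1.0 by convention (nothing asserted, nothing wrong).
    """
    tp, fp, fn = len(cs.tp), len(cs.fp), len(cs.fn)
    precision = 1.0 if tp + fp == 0 else tp / (tp + fp)
    recall = 1.0 if tp + fn == 0 else tp / (tp + fn)
    return precision, recall


def jaccard(A: DomainOfInfluence | Iterable, B: DomainOfInfluence | Iterable) -> float:
    """|A∩B| / |A∪B|; 1.0 when both sets are empty (convention)."""
    a = frozenset(A.members if isinstance(A, DomainOfInfluence) else A)
    b = frozenset(B.members if isinstance(B, DomainOfInfluence) else B)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected (average-rank) Spearman rank correlation."""
    if len(x) != len(y):
        raise ValueError("size lists differ in length")
    res = stats.spearmanr(x, y)
    return float(res.statistic)


# --------------------------------------------------------------------------
# Seed-set enumeration and sampling


def seed_sets(
    net: BooleanNetwork,
    size: int,
    n_samples: int = 1000,
    rng: np.random.Generator | int | None = None,
    allow_any_size: bool = False,
) -> list[SeedSet]:
    """Seed sets of a given size over distinct nodes.

    Size 1 enumerates all ``2N`` singletons; sizes 2 and 3 draw
    ``n_samples`` distinct sets uniformly over the
    ``C(N, size) * 2**size`` valid (contradiction-free, distinct-node)
    sets — or enumerate them all when fewer exist.
    """
    if size not in (1, 2, 3) and not allow_any_size:
        raise ValueError("seed-set size must be 1, 2 or 3 (or allow_any_size=True)")
    if size < 1 or size > net.N:
        raise ValueError(f"invalid seed-set size {size} for N={net.N}")
    if size == 1:
        return [SeedSet.from_pairs([(n, v)]) for n in net.nodes for v in (0, 1)]
    total = math.comb(net.N, size) * 2**size
    if total <= n_samples:
        out = []
        for combo in itertools.combinations(net.nodes, size):
            for bits in itertools.product((0, 1), repeat=size):
                out.append(SeedSet.from_pairs(zip(combo, bits)))
        return out
    rng = np.random.default_rng(rng)
    seen: set[frozenset] = set()
    out = []
    while len(out) < n_samples:
        nodes = rng.choice(net.N, size=size, replace=False)
        bits = rng.integers(0, 2, size=size)
        pins = frozenset((net.nodes[i], int(b)) for i, b in zip(nodes, bits))
        if pins in seen:
            continue
        seen.add(pins)
        out.append(SeedSet(pins))
    return out


# --------------------------------------------------------------------------
# Benchmark


@dataclass
class BenchmarkReport:
    """Per (method, seed-set size) aggregate metrics of a benchmark run.

    ``table`` has one row per stratum with mean domain size, precision,
    recall, Jaccard similarity, Spearman rho of predicted vs true sizes
    and mean wall time per seed set (GTN build time amortized).
    """

    table: pd.DataFrame
    params: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def to_csv(self, timing: bool = True) -> str:
        df = self.table
        if not timing:
            df = df.drop(columns=[c for c in df.columns if c.startswith("time")])
        return df.to_csv(index=False)

    def to_json(self, timing: bool = True) -> str:
        df = self.table
        if not timing:
            df = df.drop(columns=[c for c in df.columns if c.startswith("time")])
        return df.to_json(orient="records", indent=1)


def run_benchmark(
    net: BooleanNetwork,
    methods: Sequence[str] = ALL_METHODS,
    sizes: Sequence[int] = (1, 2, 3),
    n_samples: int = 1000,
    T: int = DEFAULT_T,
    R: int = DEFAULT_R,
    tolerance: float = DEFAULT_TOL,
    gt_mode: str = "auto",
    rng: np.random.Generator | int | None = None,
    network_name: str = "network",
) -> BenchmarkReport:
    """Run all requested estimators against the ground truth.

    GTNs are built once per representation and their build time is
    amortized over the seed sets of each stratum.  Per-seed-set failures
    are recorded in the report rather than aborting the run.
    """
    for m in methods:
        if m not in ALL_METHODS:
            raise ValueError(f"unknown method {m!r}")
    rng = np.random.default_rng(rng)
    universe = pair_universe(net)

    gtns = {}
    build_time = {}
    for m in methods:
        if m in GTN_METHODS:
            t0 = time.perf_counter()
            gtns[m] = build_gtn(net, m)
            build_time[m] = time.perf_counter() - t0

    rows = []
    failures = []
    for size in sizes:
        sets = seed_sets(net, size, n_samples=n_samples, rng=rng)
        acc = {m: {"size": [], "precision": [], "recall": [], "jaccard": [], "time": []}
               for m in methods}
        gt_sizes = []
        for X in sets:
            try:
                _, D = ground_truth(net, X, T=T, R=R, mode=gt_mode, rng=rng)
            except Exception as exc:  # pragma: no cover - defensive
                failures.append((str(X), "GT", repr(exc)))
                continue
            gt_sizes.append(len(D))
            for m in methods:
                try:
                    t0 = time.perf_counter()
                    if m in GTN_METHODS:
                        DZ = doi_bfs(gtns[m], X)
                    else:
                        DZ = ibmfa_doi(net, X, T=T, tolerance=tolerance)
                    elapsed = time.perf_counter() - t0
                except Exception as exc:  # pragma: no cover - defensive
                    failures.append((str(X), m, repr(exc)))
                    continue
                cs = confusion(D, DZ, universe)
                p, r = precision_recall(cs)
                acc[m]["size"].append(len(DZ))
                acc[m]["precision"].append(p)
                acc[m]["recall"].append(r)
                acc[m]["jaccard"].append(jaccard(D, DZ))
                acc[m]["time"].append(elapsed)
        for m in methods:
            a = acc[m]
            n = len(a["size"])
            if n == 0:
                continue
            amortized = build_time.get(m, 0.0) / len(sets)
            rho = (
                spearman_rho(a["size"], gt_sizes)
                if len(set(a["size"])) > 1 and len(set(gt_sizes)) > 1
                else float("nan")
            )
            rows.append(
                {
                    "network": network_name,
                    "method": m,
                    "seed_size": size,
                    "n_seed_sets": n,
                    "mean_gt_size": float(np.mean(gt_sizes)),
                    "mean_size": float(np.mean(a["size"])),
                    "mean_precision": float(np.mean(a["precision"])),
                    "mean_recall": float(np.mean(a["recall"])),
                    "mean_jaccard": float(np.mean(a["jaccard"])),
                    "spearman_rho": rho,
                    "time_per_seed_set": float(np.mean(a["time"]) + amortized),
                    "time_build": build_time.get(m, 0.0),
                }
            )
    table = pd.DataFrame(rows)
    params = {
        "methods": list(methods),
        "sizes": list(sizes),
        "n_samples": n_samples,
        "T": T,
        "R": R,
        "tolerance": tolerance,
        "gt_mode": gt_mode,
    }
    return BenchmarkReport(table=table, params=params, failures=failures)


# --------------------------------------------------------------------------
# Ground-truth sub-sampling experiment


def subsample_experiment(
    net: BooleanNetwork,
    X: SeedSet,
    p_list: Sequence[float] = (0.01, 0.10, 0.25, 0.50, 0.75),
    T: int = DEFAULT_T,
    rng: np.random.Generator | int | None = None,
    max_free: int = 14,
) -> pd.DataFrame:
    """Compare sub-sampled ground truth ``D_p`` with the exhaustive ``D``.

    For each fraction ``p``, ``R = ceil(p * 2**(N - |X|))`` initial
    configurations are sampled (with replacement; exhaustive enumeration
    is used when the sample covers the whole free state space) and the
    resulting domain is scored against the exhaustive one.  A node
    constant over every configuration is constant over any subsample
    with the same value, so ``D`` is always contained in ``D_p``: recall
    is 100% by construction (verified), similarity equals precision, and
    the sub-sample can only overestimate the domain.
    """
    n_free = net.N - len(X)
    if n_free > max_free:
        raise ValueError(
            f"free state space 2**{n_free} too large for exhaustive truth"
        )
    rng = np.random.default_rng(rng)
    universe = pair_universe(net)
    _, D = ground_truth(net, X, T=T, mode="brute")
    rows = []
    for p in p_list:
        R = math.ceil(p * 2**n_free)
        if R >= 2**n_free:
            _, Dp = ground_truth(net, X, T=T, mode="brute")
        else:
            _, Dp = ground_truth(net, X, T=T, R=R, mode="sample", rng=rng)
        cs = confusion(D, Dp, universe)
        precision, recall = precision_recall(cs)
        if recall != 1.0 or len(Dp) < len(D):
            raise RuntimeError(
                "sub-sampled domain lost a truly constant node; "
                "this indicates an internal simulation inconsistency"
            )
        rows.append(
            {
                "p": p,
                "R": R,
                "size_exhaustive": len(D),
                "size_subsample": len(Dp),
                "jaccard": jaccard(D, Dp),
                "precision": precision,
                "recall": recall,
            }
        )
    return pd.DataFrame(rows)
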