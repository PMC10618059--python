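# booldoi

Domains of influence of pinned node sets in synchronously updated Boolean
networks.

Boolean networks are the workhorse models of gene regulation and cell
signalling: each node `i` carries a binary state `σ_i(t)` and updates
synchronously via a transfer function `F_i` of its inputs. Pinning a *seed
set* `X = {(i, σ̂_i)}` — holding a few nodes at fixed values for all time, as
a drug or knockout would — can force other nodes into deterministic long-term
states. The set of all such (node, state) pairs is the **domain of
influence** `D(X)`, the central object of target control: it tells you which
genes or proteins a small intervention actually decides.

Computing `D(X)` exactly requires averaging over all `2^(N−|X|)` initial
configurations, which is infeasible beyond small `N`. This package
implements and benchmarks the practical estimators side by side:

- **Ground truth** — the definition itself: the ensemble mean state
  `σ̄_i(T) = (1/R) Σ_r σ_i^(r)(T)` at horizon `T` (default 10) over all, or
  `R` sampled, initial configurations; `D(X) = {(i, σ̄_i(T)) : σ̄_i(T) ∈ {0,1}}`.
- **Generalized threshold networks (GTN)** — a static directed graph with
  `2N` state nodes (`i-0`, `i-1`) and integer-threshold gates encoding every
  state transition. Three builders differ only in how `F_i` is represented:
  the raw look-up table (**LUT**, one τ = k gate per row — a worst-case
  baseline attaining the size bounds `M = Σ 2^{k_i}`,
  `E = Σ (k_i+1) 2^{k_i}`), the syntactic disjunctive normal form (**DNF**,
  one gate per clause), and the two-symbol schema redescription (**SR**,
  layered gates expressing "at least m of these inputs active", built from
  Quine–McCluskey prime implicants). A two-queue breadth-first search from
  the seed state nodes then yields `D_Z(X)` by exact logical inference —
  sound by construction (perfect precision), but conservative.
- **Individual-based mean-field approximation (IBMFA)** — iterate activation
  probabilities `s_i(t) = Σ_n δ(1, F_i(n)) Π_j s_j(t−1)^{n_j} (1−s_j(t−1))^{1−n_j}`
  from `s_i(0) = 1/2`, treating inputs as independent; nodes whose `s_i(T)`
  reaches 0 or 1 form `D_IBMFA(X)`. Better recall, imperfect precision.

An evaluation harness (precision/recall/Jaccard over the `2N` node-state
pairs, Spearman rank correlation of domain sizes, seed-set enumeration and
sampling, a ground-truth sub-sampling experiment, timing) and a random
Boolean network generator round out the package.

## Worked example

The bundled four-node toy network has three environmental inputs `a, b, c`
and one target `d = (a AND c) OR (b AND c)`. Pin `X = {a=1, c=1}`:

```python
from booldoi import (SeedSet, build_gtn, doi_bfs, ground_truth, ibmfa_doi,
                     size_bounds, transfer_subgraph)
from booldoi.synthetic import toy_network

net = toy_network()
X = SeedSet.from_string("a=1,c=1")
print("network size N =", net.N, "| size bounds (M, E) =", size_bounds(net))
for rep in ("LUT", "DNF", "SR"):
    g = build_gtn(net, rep)
    sub = transfer_subgraph(g, "d", 1)
    D = doi_bfs(g, X)
    print(f"{rep:4s} activation portion of d-1: {sub.number_of_nodes()} nodes, "
          f"{sub.number_of_edges()} edges | D_{rep}(X) = {sorted(D.members)}")
means, D = ground_truth(net, X, mode="brute", T=10)
print("ground truth   D(X) =", sorted(D.members), "| mean state of b:", means["b"])
print("mean-field D_IBMFA(X) =", sorted(ibmfa_doi(net, X, T=10).members))
```

prints

```
network size N = 4 | size bounds (M, E) = (14, 44)
LUT  activation portion of d-1: 9 nodes, 12 edges | D_LUT(X) = [('a', 1), ('c', 1)]
DNF  activation portion of d-1: 6 nodes, 6 edges | D_DNF(X) = [('a', 1), ('c', 1), ('d', 1)]
SR   activation portion of d-1: 6 nodes, 5 edges | D_SR(X) = [('a', 1), ('c', 1), ('d', 1)]
ground truth   D(X) = [('a', 1), ('c', 1), ('d', 1)] | mean state of b: 0.5
mean-field D_IBMFA(X) = [('a', 1), ('c', 1), ('d', 1)]
```

Read this as: the raw-LUT representation needs all three of `d`'s inputs
before it can conclude anything, so pinning only `a` and `c` teaches it
nothing about `d` — while the DNF clause `{a=1, c=1}` (threshold 2) and the
SR schema "`c` active and at least one of `{a, b}` active" both fire, and
both match the exhaustive ground truth: `d` is driven active, `b` stays
maximally uncertain (mean 0.5). The SR graph is also the most concise
encoding of `d`'s activation logic (5 edges vs 12 for the LUT).

The same operations are available from the shell:

```sh
booldoi generate --n 8 --k 2 --seed 1 -o rbn.txt
booldoi doi rbn.txt --seeds "n0=1" --method SR
booldoi benchmark rbn.txt --sizes 1,2 --seed 0
```

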