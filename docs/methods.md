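# Methods

## Model and problem

A Boolean network `B` has `N` nodes with binary states `σ_i(t)` updated
synchronously: `σ_i(t) = F_i(σ_{N_i}(t−1))`, where `N_i` is node `i`'s
ordered input list and `F_i` its transfer function, representable either as
a logical expression over AND/OR/NOT or as a complete look-up table (LUT)
with `2^{k_i}` rows (`k_i = |N_i|`). Rows are ordered by reading the input
tuple as a binary number, first input most significant; this canonical order
fixes all serializations. Environmental inputs — nodes that never receive a
rule — are modelled as arity-1 identity self-loops, which makes their state
time-invariant while keeping every node rule-governed; a switch on the
threshold-network builders (`input_logic=False`) omits their logic for
pure-source semantics.

A *seed set* `X` pins nodes to fixed values for all `t ≥ 0` (pins override
the transfer function in every estimator, including at `t = 0`). The
*domain of influence* `D(X)` is the set of (node, state) pairs whose
long-term state becomes deterministic under the pinning, averaged over the
`2^{N−|X|}` equiprobable initial configurations of the unpinned nodes.
`X ⊆ D(X)` always.

## Ground truth

`ground_truth` simulates the ensemble: exhaustively when the free state
space has at most `2^10` configurations (mode `auto`), otherwise with `R`
(default 100) i.i.d. uniform initializations drawn with replacement (a
warning fires if `R` exceeds the state-space size). Membership in `D(X)` is
decided at the single horizon `T` (default 10) by exact integer counts —
a node is in the domain iff *every* realization agrees at `T` — never by
floating-point comparison of means. `T = 10` is the conventional horizon for
networks of this scale; it is exposed everywhere. A node on a limit cycle
whose ensemble happens to agree at `T` is admitted by this single-time
definition; the optional `window=w` mode additionally demands constancy over
`[T, T+w]` and can only shrink the domain. The default follows the
single-time definition.

The ensemble loop runs on a compiled array form of the network (all `R`
configurations stepped at once with numpy gather/LUT-indexing); the
dict-based `step`/`trajectory` functions are the readable reference
implementation, and the test suite cross-checks the two paths row by row.

## Transfer-function representations

`to_dnf` is purely syntactic: negations are pushed to the literals by De
Morgan and AND is distributed over OR. Clauses are *not* minimized —
representing an expression as given is part of what the DNF representation
means here — except that duplicate clauses and internally contradictory
clauses are dropped. Distribution can explode combinatorially, so an
intermediate-clause cap (default `2^16`) raises `DNFBlowupError` rather than
hang.

`prime_implicants` is a textbook Quine–McCluskey implementation on the LUT:
iterative merging of one-bit-adjacent implicants, keeping every implicant
that survives unmerged. All prime implicants are returned (no minimal-cover
selection); their expansions union to exactly the rows with the requested
output.

`redescribe` computes the two-symbol schema form: prime implicants sharing a
symbol multiset are clustered by transposition adjacency (two patterns that
differ by swapping exactly two symbols); a cluster collapses to a schema
with position-free groups when its varying positions partition into blocks
whose per-implicant multiset is `m` copies of one value plus wildcards *and*
the cluster contains exactly every arrangement (verified by generating the
product of arrangements and comparing). Only "at least `m` of these members
at value `v`" groups are emitted, because that is precisely what a threshold
gate can encode; clusters with more exotic permutation structure fall back
to ungrouped fixed-only schemas, which preserves the module's contract: the
union of schema expansions always equals the LUT rows with the given
output. Whether schemas are derived from the LUT or from the expression is
immaterial semantically; the LUT route is implemented. Outputs are emitted
in lexicographic order of their symbol strings for reproducibility.

## Generalized threshold networks

A GTN has `2N` state nodes plus threshold gates; a gate fires when at least
`τ` of its predecessors are satisfied. Builders:

- **LUT** — per node and output value, one gate per matching row, `τ = k_i`,
  fed by each input's matching state node. This attains the size bounds
  `M = Σ_i 2^{k_i}` and `E = Σ_i (k_i+1) 2^{k_i}` with equality (asserted in
  tests), making it the worst-case baseline.
- **DNF** — one gate per clause, `τ` = clause length, for the expression and
  its negation. LUT-only nodes fall back to prime-implicant clauses
  (disable with `qm_fallback=False`). Single-literal clauses still get a
  `τ = 1` gate: no state→state edges exist in any GTN.
- **SR** — per schema, one *group* gate per position-free group (`τ = m`,
  inputs = the members' state nodes at the group value) feeding a *final*
  gate together with the fixed literals (`τ` = number of fixed non-wildcard
  literals + number of groups).

Arity-0 (constant) transfer functions get a degenerate `τ = 0` gate with no
inputs — the only place the `1 ≤ τ ≤ in-degree` rule is relaxed, since a
constant has no inputs to threshold over. Gate identifiers are deterministic
(`node|value|index`), so exports (JSON and TSV edge list, both
round-trippable) are byte-stable. `verify_gtn` checks logical completeness
exhaustively: for every node and every input assignment, exactly one of
`i-0`/`i-1` is derivable and equals `F_i`.

## Inference and the mean-field estimator

`doi_bfs` implements the two-queue search: the current queue is drained one
element at a time into the visited set; threshold gates whose `τ` is met by
satisfied predecessors are processed immediately within the current stage,
while newly implied state nodes wait for the next stage, so state-node
levels correspond to time steps of forced dynamics. Threshold satisfaction
counts *all* satisfied predecessors — state nodes and already-fired group
gates — which the layered SR gates require. State nodes contradicting an
already-derived state are skipped (and logged at debug level), never added.
Soundness follows by induction on levels: every inference is a consequence
of the pins, so the BFS domain is contained in the exhaustive ground truth
whenever the horizon `T` covers the BFS depth — the perfect-precision
property asserted over a random ensemble in the tests.

`ibmfa_run` iterates `s_i(t) = Σ_n δ(1, F_i(n)) Π_j s_j(t−1)^{n_j}
(1−s_j(t−1))^{1−n_j}` with `s_i(0) = 1/2` off-seed and pins held fixed, at
cost `O(Σ_i 2^{k_i})` per step. The independence assumption is exact when no
node receives correlated inputs (single-input chains/trees; asserted against
the exhaustive average to 1e−12). `ibmfa_doi` admits nodes with
`|s_i(T)| ≤ tol` or `|s_i(T) − 1| ≤ tol`, `tol = 1e−9`: products of exact
0/1 pins propagate exactly in binary floating point, so the tolerance only
guards accumulated rounding, not model error.

## Evaluation harness

Confusion sets are computed over the universe of all `2N` (node, state)
pairs; precision is defined as 1.0 for an empty prediction and recall as 1.0
for an empty truth (nothing asserted, nothing wrong). Jaccard of two empty
sets is 1.0. Spearman's rank correlation uses average ranks under ties
(scipy) and is reported as NaN for constant size lists.

Seed sets of size 1 are enumerated exhaustively (all `2N`); sizes 2–3 are
sampled uniformly without duplicates over distinct nodes (a set pinning the
same node twice is either contradictory or not of that size), falling back
to full enumeration when fewer valid sets exist than requested.

`run_benchmark` builds each requested GTN once and amortizes the build time
over the seed sets of a stratum; wall times are reported but never asserted
(hardware-dependent). Per-seed-set failures are collected in the report
rather than aborting. With fixed seeds the non-timing columns of the report
are byte-identical across runs.

`subsample_experiment` contrasts the exhaustive domain `D` with `D_p`
estimated from `R = ceil(p · 2^{N−|X|})` sampled configurations. A node
constant over every configuration is constant (with the same value) over any
subsample, so `D ⊆ D_p` and recall is 100% by construction — the function
verifies this invariant and reports size, Jaccard and precision per `p`.
Draws are with replacement; when the requested sample covers the whole free
state space (`p = 1`) the exhaustive enumeration is used, so `D_1 = D`.

## Synthetic generators

`toy_network()` is the four-node fixture (three identity inputs and
`d = (a AND c) OR (b AND c)`, with `inputs(d) = [a, b, c]` so the LUT's
three active rows are `011, 101, 111`). `random_network(RBNSpec(...))`
draws classic N-K networks: `K` distinct inputs per node uniformly (self
allowed by default), each LUT row active independently with probability
`bias` (default 0.5, the maximally heterogeneous choice). `chain_network(L)`
builds copy chains for the mean-field exactness oracle. The default test
ensemble uses `N ∈ {4..8}`, `K ∈ {1..3}`, bias 0.5 — small enough for
exhaustive ground truth, rich enough to exercise every representation.
These generators emulate rule-based regulatory models structurally; they do
not reproduce the canalizing, low-bias functions typical of curated
biological models, so passing tests demonstrate correctness of the
machinery, not field performance on real networks. The sub-sampling study
runs at `N = 10` with a single pinned node and 50 replicate RNG seeds, sizes
chosen so exhaustive truth stays instantaneous.

## Numerical and design choices

- Tie-breaks: clauses, implicants, schemas and gate ids are emitted in
  deterministic sorted order; all sampling flows through
  `numpy.random.default_rng` seeds.
- Domain membership in the ground truth uses integer counts (`0` or `R`),
  immune to float accumulation.
- `BooleanNetwork` validation cross-checks expression vs LUT exhaustively up
  to arity 12; beyond that, agreement is taken on trust.
- Rule-file writing preserves arity for constant LUT nodes by emitting
  tautologies/contradictions over the declared inputs, so
  `parse(write(net))` reproduces every LUT and input list exactly.
- The edge-list GTN export infers the group/final layer tag on re-import
  from whether a gate feeds another gate; the JSON export stores it
  explicitly.

## Known limitations

- Synchronous update only; the BFS inference stays sound for any update
  scheme that preserves its level order, but no other scheme is implemented.
- Boolean variables only (the GTN data structure could host multi-valued
  states; the builders do not).
- DNF conversion and schema redescription are worst-case exponential in
  arity; the clause cap fails loudly rather than degrade.
- The single-time domain definition can admit oscillating nodes whose
  ensemble happens to agree at `T`; use `window` to exclude them.
- No attractor enumeration and no search for minimal controlling seed sets —
  the package scores given seed sets, it does not design them.
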