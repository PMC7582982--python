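# Methods

## The dynamics model

A directed network encodes information dependencies among subproblems: an arc
`j → i` means subproblem `i` consumes information produced by `j`. Each node
is binary, *open* (unresolved) or *closed* (resolved). Time advances in
single-node updates: at each step one node is chosen uniformly at random.

* Closed node with `k` open in-neighbors: reopens with probability
  `1 − (1−β)^k` — each open upstream subproblem independently forces a
  reopening with probability `β`.
* Open node: closes with probability `(1−β)^k · δ` — it must escape every
  open in-neighbor's influence (each escape has probability `1−β`) and then
  resolve itself in a self-directed way (probability `δ`).

Both parameters are probabilities in `[0, 1]`, homogeneous across nodes.
`β` is the *reopening probability* (coupling strength of upstream churn),
`δ` the *self-directed probability* (rate of autonomous progress). The
all-closed configuration is absorbing: with every node closed, `k = 0`
everywhere and nothing can reopen. Reaching it is *full synchronization*.

**Influence set.** The reopening rule explicitly acts through incoming
links. The closing rule's "neighboring open nodes" is read the same way —
open *in-neighbors* — for consistency of the information-flow picture. An
undirected variant (any arc is an influence channel) is available via
`undirected_influence`, but it is not the default: under the undirected
reading the closing and reopening pressures become symmetric in a way that
collapses the score differences between feedback-free and feedback-rich
subgraphs and contradicts the qualitative behavior the model is meant to
capture (the feedforward loop outperforming mutual dyads and cliques).

**Time units.** One "iteration" is one single-node update; a sweep of an
`n`-node network is `n` iterations. All protocol sizes below count
single-node updates.

**Initial state.** All-open by default (solving from scratch); all-closed
and random starts are available through `SimulationConfig.initial_state`.

## SM scores

The synchronizability metric (SM) of a subgraph is the probability of full
synchronization within `T` updates, averaged over parameter uncertainty:

    SM = E_{(β,δ) ~ U(0,1)²} [ P(sync within T | β, δ) ]

estimated with `S` parameter samples × `R` realizations each, all-open
start. Library defaults are the full protocol `S = 10,000`, `R = 100`,
`T = 120`; the `sm` and `catalog` CLI subcommands default to `S = 1,000`
for interactive latency (pass `--samples 10000` for the full protocol).
`T = 120` is used for both 3- and 4-node classes for comparability. Each
class receives an independent child RNG stream spawned from the config seed,
so results are reproducible and independent of evaluation order. The
reported standard error is the standard error of the mean over the `S`
per-sample probabilities; it is dominated by the parameter-sampling
variance, not the realization noise.

**Resolution limits.** The exact expectation (computable for 3-node classes
by iterating the 8-state Markov chain and integrating over the unit square
by Gauss–Legendre quadrature — implemented as the test oracle) shows the 13
scores form tiers separated by gaps of 0.03–0.13, but with two near-tied
blocks inside them: the top block (in-star, out-star, cascade, feedforward
loop; internal gaps 0.0005–0.009) and the mutual-dyad block (mutual-in,
mutual-out, regulated mutual, regulating mutual; total spread 0.0024).
No finite Monte-Carlo protocol of practical size orders these blocks
reliably — at `S = 1,000` the per-class standard error is ≈ 0.006–0.013 —
so analyses built on SM ranks should treat within-block order as arbitrary.
A useful structural fact: adding an arc to a subgraph can only add
reopening pressure, so SM is non-increasing along sub-digraph containment;
any claimed ordering that ranks a supergraph above one of its sub-digraphs
(e.g. the regulated mutual above the mutual-in) is a noise artifact.

Quartiles of the SM scores (linear-interpolation quartile convention)
define four synchronizability classes: 4 = `score ≥ Q3`, 3 = `[median, Q3)`,
2 = `[Q1, median)`, 1 = `< Q1`. With all-equal scores every value lands in
class 4 (the `≥ Q3` branch).

**Conventional class IDs.** Classes are numbered 1..N by descending SM
score (ID 1 = most synchronizable); ties break by ascending arc count, then
canonical code, so IDs are reproducible under reruns. The catalog's internal
order (arc count, then canonical code) is deterministic and independent of
any SM run.

## Census and canonicalization

Canonical form of a small digraph is the lexicographically smallest sorted
arc tuple over all node relabelings — brute force, exact, and cheap at
`k ≤ 4` (at most 24 permutations). Census counts are *induced*: every
k-node subset whose induced subgraph is weakly connected contributes exactly
one occurrence of one class, the standard motif-census convention. Counting
over subsets (not embeddings) needs no symmetry-factor corrections.
Enumeration is ESU-style neighborhood expansion, so only connected subsets
are visited; each induced subgraph is classified in O(1) through a
precomputed arc-bitmask table (4,096 entries for `k = 4`). A brute-force
`C(n, k)`-subset oracle with permutation canonicalization cross-checks the
fast path in the tests.

## Null model and significance

The null ensemble is uniform `G(n, m)`: exactly `m` distinct ordered pairs
drawn uniformly, no self-loops, mutual arcs allowed, no connectivity
constraint — matched to each real network's node and arc counts. Defaults:
500 random networks per ensemble; per-class standard deviation is the
population standard deviation over the ensemble.

* `Z_i = (N_real,i − ⟨N_rand,i⟩) / σ_rand,i`; `σ = 0` makes the entry
  undefined (flagged, NaN) — typical for the densest classes of sparse
  networks.
* Significance profile `SP`: the Z vector scaled to unit Euclidean norm over
  defined entries.
* `RD_i = (N_real,i − ⟨N_rand,i⟩) / (N_real,i + ⟨N_rand,i⟩) ∈ [−1, 1]`;
  a 0/0 (class absent from both) is undefined and flagged. The normalized
  RD profile uses the same unit-norm convention.

Cross-network profile comparisons drop any network carrying an undefined
entry (whole-network exclusion); pair-by-pair exclusion is available behind
a flag. A statistical caveat encoded in the tests: Z-scores computed against
a fixed finite ensemble of size `E` carry a mean-estimate error of order
`1/√E` in Z units that does not average out over repeated real networks.

## Rank statistics

Spearman correlation is Pearson on average ranks (ties share their rank
range's mean), with a two-tailed p-value from the `t` approximation with
`n − 2` degrees of freedom (`p = 0` at `|ρ| = 1`). Kruskal–Wallis uses the
tie-corrected `H` with a chi-squared p-value on `groups − 1` degrees of
freedom. Both statistics are computed in-package on ranks; scipy supplies
only the distribution functions, and agreement with scipy's implementations
to 1e-10 is asserted in the tests. Box-plot summaries use
linear-interpolation quartiles; whiskers extend to the most extreme values
within `1.5 × IQR` of the box and anything beyond is an outlier. Tests that
are degenerate for a grouping (e.g. a single-class density group) are
reported as missing rather than raising.

## Data formats

Edge lists: two columns (source, target), `#` comments, whitespace or
explicit delimiter; nodes appear in first-encounter order; self-loops are
dropped and duplicate arcs collapsed, each with a logged warning (DSM
exports sometimes repeat entries). `#node X` comments preserve isolated
nodes across round trips. DSM files: square binary CSV, optional label
header row/column auto-detected, diagonal ignored with a warning. The
default orientation is row-depends-on-column (a mark at row `i`, column `j`
yields the information-flow arc `j → i`), the common DSM convention;
`column-depends-on-row` flips it, since published matrices differ.

## Synthetic networks

`gen_er(n, m, seed)` draws exactly `m` distinct ordered pairs uniformly.
`plant_motifs` overlays copies of a class on disjoint node sets chosen by a
seeded permutation, so the planted class's census count is at least the copy
count (exact on an empty base). Named fixtures provide the reference 3-node
subgraphs (feedforward loop, mutual-in, mutual cascade, clique, cascade,
feedback loop, semi-clique) and a fixed 10-node toy network shipped as a
matching DSM/edge-list file pair. Synthetic ER and planted networks emulate
only the size, density and planted excesses of real dependency networks —
not their hubs, degree asymmetry or modular structure — so passing tests
demonstrate correctness of the machinery and recovery of planted signal,
not conclusions about real problem-solving data.

## Problem sizes used in the test suite

The suite favors exact oracles and paired constructions over brute
replication: SM ranking checks run `S = 1,000 × R = 100 × T = 120`;
oracle-equivalence census checks use 100 seeded graphs with `n ≤ 12`;
self-null Z checks use 150 repetitions against a 300-network ensemble
(`n = 18`, `m = 50`); planted-motif recovery uses an ER(60, 120) base with
{0, 5, 10, 20} planted feedforward loops and 20 replicate 100-network
ensembles. Near-tied SM blocks are asserted score-wise within 3 combined
standard errors rather than by exact rank, for the resolution reasons above.

## Known limitations

* Subgraph sizes are capped at 4 (the catalog approach is exact but
  exponential); censuses are exact, with no sampling mode for very large
  networks.
* The null model is ER only; degree-preserving randomizations are out of
  scope.
* Mean-field or analytic treatments of the dynamics on large networks are
  out of scope; exact absorption probabilities are used only as small-graph
  test oracles.
* Heterogeneous per-node `(β, δ)` is accepted by the simulator's interface
  design but not used by SM scoring.
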