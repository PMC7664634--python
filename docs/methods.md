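# Methods

## Model and scope

A discrete Bayesian network is a DAG `G` over categorical variables
`X_1..X_n` with a conditional probability table (CPT) per variable; the
joint factorises as `P(X_1..X_n) = Π_i P(X_i | pa(X_i))`. `blockbn`
learns `G` from a complete-case sample of size `N` (no missing entries:
all scores below are pure count expressions and would be undefined
otherwise). Parameter learning beyond maximum-likelihood counts, and
inference on the learned network, are out of scope.

The learner assumes the *sparse-block* regime: dependencies concentrate
inside communities of variables, with few cross-community edges. All
guarantees below are conditional on that premise — with many cross-block
skeleton edges the `2^m` orientation enumeration is deliberately stopped
by a cap rather than silently exploding.

## Scoring conventions

Everything is in **nats** (natural log). One base must be used
consistently so the entropy term and the complexity penalty of the MDL
score are commensurate; natural log is used throughout (MI, G², MDL,
BIC).

Node score (lower is better), from raw counts with `0·log 0 := 0` and no
smoothing:

```
MDL(X|PA) = H(X|PA) + (log N / 2) · K(X|PA)
H(X|PA)   = − Σ_{x,pa} N_{x,pa} · log(N_{x,pa} / N_{pa})
K(X|PA)   = (r_X − 1) · Π_{L∈PA} r_L
```

`H` is the count-scaled empirical conditional entropy, so the total MDL
decomposes as `MDL(G) = Σ_i MDL(X_i | PA_i)` exactly. The BIC used for
final model selection is `loglik − (d/2) log m` with
`loglik = −Σ_i H(X_i|PA_i)` and `d = Σ_i K(X_i|PA_i)`; hence
`BIC = −MDL` identically, and maximising BIC across candidates equals
minimising total MDL. Published BIC tables for networks of this size are
usually sample-normalised (magnitudes of a few nats), so
`BicScore.per_sample = raw / m` is reported alongside the raw value;
only the identities, not any external magnitude, are asserted by tests.

## MI K-medoid blocking (`mkm`)

Similarity between variables is plug-in mutual information; assignment
sends each variable to the medoid of **maximal** MI (higher = more
dependent). MI is treated strictly as a similarity, not a metric — the
triangle-type inequality holds only under a Markov-chain condition, and
nothing here relies on it. The block cost is
`Σ_{x∈C, x≠medoid} I(x; medoid)`; total cost is maximised. A full
assignment sweep alternates with a full medoid-replacement sweep (any
member whose promotion strictly raises the block cost becomes the
medoid); both steps are monotone in total cost, so the loop terminates —
`max_iter = 100` is a pure safety net.

Choices the algorithm family leaves open, fixed here:

- **Initialisation**: uniform random distinct medoids from the seed;
  `plusplus_init=True` instead spreads starts by repeatedly picking the
  variable with the weakest maximal MI to the chosen medoids. K-medoid
  is a local search and the plain random start occasionally lands in a
  poor basin (visible in the restart-quality test at ~8% of restarts);
  the spread start avoids the observed pathologies.
- **Ties / isolated variables**: max-MI ties and all-zero-MI variables go
  to the lowest-index medoid, deterministically.
- **k is a required input** (the heuristic `round(sqrt(p/2))` is offered
  by `suggest_k` and by the CLI when `--k` is omitted, but the library
  never applies it silently).

## MMPC skeleton (`mmpc`)

Association between `X_i` and a candidate `X_j` given subset `S` is the
G² statistic `2N·I(X_i;X_j|S)` referred to the chi-square upper tail
with `df = (r_i−1)(r_j−1)·#{observed configurations of S}` —
conditioning configurations with zero count contribute neither to the
statistic nor to the df (df floored at 1). Smaller p-value = stronger
association; ties break toward larger G².

Forward phase: add the candidate whose *minimum* association over
conditioning subsets of the current PC (subset size ≤ `max_cond`,
default 3) is strongest, while that minimum is significant at `alpha`
(default 0.05). Backward phase: drop any member some subset renders
independent. The skeleton places an edge only when membership is mutual
(**AND rule**) — the conservative choice that underwrites the
no-added-edges behaviour downstream. A `pc_cap` (default 10) bounds the
exponential test count of the forward phase with a logged warning.

Under full independence the per-pair false-edge rate is ≈ `alpha` (the
two directed marginal tests of a pair share one statistic, so the AND
rule does not suppress marginal false positives); the type-I test
asserts exactly this binomial behaviour rather than an all-empty
skeleton, which arithmetic rules out at `alpha = 0.05` for more than a
couple of variables.

## Orientation enumeration and forced parents (`combiner`)

Cross-block skeleton edges are enumerated in lexicographic order and all
`2^m` direction assignments generated by binary counting (bit `e` set =
edge `e` reversed). The cap (default 16 → 65 536 candidates) turns a
violated sparsity premise into a diagnosable error suggesting a coarser
blocking.

For a directed cross edge `u → v`, `u` is a **forced external parent** of
`v` in `v`'s block problem: it appears in every parent configuration
evaluated for `v` (contributing to both `H` and `K`) but is not a node
of the block's DAG — the skeleton asserted the adjacency and the
candidate fixes its direction, so treating it as optional would let the
block search contradict the candidate being scored. A config switch
(`forced_mandatory=False`) downgrades cross parents to ordinary
candidates for sensitivity analysis.

Orientations through several blocks can compose into a directed cycle
even though each block DAG is acyclic. Intra-block directions are
unknown until the exact search runs, so the only sound filter is
post-hoc: cyclic assemblies are discarded at selection time, counted,
and logged. (The worked example in the README shows 2 of 8 candidates
discarded this way.)

## Pruned dynamic programming (`dp`)

Per variable, a **parent graph** over subsets of its candidate parents
caches `BestMDL(X,P) = min_{S⊆P} MDL(X|S)` bottom-up; candidates are
pruned to skeleton neighbours. The **order graph** over variable subsets
then applies `MDL(O ∪ {X}) = MDL(O) + BestMDL(X, O ∩ cand(X))`,
realised as two layered tables (an in-memory layering; no out-of-core
writes). Reconstruction follows backpointers; `2^p` subsets are
expanded for a `p`-variable block, and a block cap (default 25) raises
an explicit error — re-block rather than wait — reflecting where plain
exact search stops being practical.

**Tie-breaking.** Markov-equivalent structures have *exactly* equal MDL
in exact arithmetic (entropy sums telescope; complexity sums coincide),
but float summation order perturbs them at ~1e-12 relative, which would
let noise pick orientations. Scores within a relative 1e-9 are therefore
treated as tied, and ties resolve deterministically: in the parent
graph, smaller score → smaller parent set → lexicographically smaller
set; in the order graph, the larger-index variable is preferred as the
later leaf. The brute-force oracle breaks score ties toward the
lexicographically smallest edge list; equivalence with the DP is
asserted as exact score agreement plus the DP structure independently
re-scoring to the oracle optimum (structure identity across the whole
equivalence class is not claimed).

`exhaustive_oracle` enumerates every admissible DAG (all topological
orders × all admissible predecessor subsets, deduplicated) and is the
package's independent cross-check; it shares no recurrence with the DP.

## Synthetic generator (`generate_block_network`)

The test-fixture backbone emulates the sparse-block regime: `b` blocks
of `nb` nodes; `round(density · C(nb,2))` intra-block edges drawn
uniformly per block and oriented low → high index; exactly
`n_inter_edges` cross-block edges drawn among cross pairs and oriented
from lower to higher block (acyclic by construction). Cardinalities are
uniform on `[2, 3]` by default. CPT rows are symmetric Dirichlet(0.5)
draws, resampled until each row's total-variation distance from uniform
is ≥ 0.1 so that every modelled dependency carries detectable signal.

Reference fixture for recovery studies: 3 blocks × 4 nodes, intra
density 0.6, 2 cross edges (~13–14 edges on 12 nodes — the edge/node
ratio of published sparse-block benchmarks of similar size), `N = 10000`
samples, 20 seeds. Under these conditions the learner attains median
`H ≤ 2` with `A = 0` in ≥ 18/20 seeds.

What the generator does **not** emulate, hence what passing tests do not
show: near-uniform (weak) CPT rows, latent confounding, deterministic
relations (faithfulness violations), unfaithful parameter cancellations,
missing data, and blocks whose community structure is ambiguous. Real
data can break the skeleton phase in all of these ways; results on the
fixture bound behaviour only under faithful, well-separated, fully
observed regimes.

## Problem sizes and numerical choices

Tests and the acceptance script use fixtures of 2–5 variables for
oracle-equivalence batches (brute-force enumeration grows as the DAG
count: 543 at 4 nodes, 29 281 at 5), 8–12 variables for pipeline
studies, and `N` between 1000 and 20 000; these sizes make every
guarantee checkable by exhaustive or well-powered means while staying
modest on a single CPU. CPT rows read from BIF are renormalised when
within 1e-6 of summing to one and rejected beyond that; CPT round-trips
hold to 1e-9. Degenerate inputs: empty variable sets score 0; a
single-state conditioning variable reduces G² df; all-constant columns
have zero MI to everything and are assigned to the lowest-index medoid.

## Known limitations

- MMPC consistency, and thus the no-added-edges guarantee *relative to
  the truth*, requires faithfulness and enough samples; `A = 0` holds
  structurally only relative to the learned skeleton.
- The `2^m` enumeration is exponential in the number of cross-block
  edges; the method is only appropriate when the blocking actually
  separates the network.
- Exact search inside a block is exponential in block size; blocks
  beyond ~20–25 variables need a larger `k`, which in turn risks more
  cross-block edges — the central trade-off of the approach.
- Orientation within a Markov equivalence class is decided by
  deterministic tie-breaks, not by data; inverted-edge counts against a
  ground truth depend on those conventions.
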