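# Methods

## Scope and model

`morseph` computes persistent homology of unweighted, undirected simple
graphs through the clique complex: the p-simplices of K are the
(p+1)-vertex complete subgraphs of G. Construction is capped at
dimension 3 by default (`cap` is a parameter everywhere); homology in the
top retained dimension is therefore *cap-sensitive* — e.g. H₃ classes of
a cap-3 complex can never be killed by 4-simplices, so top-dimension
output should be read as a property of the truncated complex, not of the
full clique complex. Coefficients are GF(2) throughout, which makes
simplex orientation irrelevant; Betti numbers of the sparse complexes
studied here are field-independent in practice, and torsion is out of
scope.

## The discrete Morse function

A function f on the simplices of K is a discrete Morse function when for
every simplex α both U_α = {cofacets β : f(β) ≤ f(α)} and
V_α = {facets γ : f(α) ≤ f(γ)} have at most one element; α is critical
when both are empty. Construction:

1. **Vertices.** g(v) = deg_max − degree(v) + ε with ε drawn per vertex
   uniformly from the open interval (0, 0.5). The inversion makes
   high-degree (structurally important) vertices cheap, so they enter
   the filtration early; the noise makes values pairwise distinct, which
   prevents equal-degree neighbours from forcing critical edges. For an
   edgeless graph deg_max = 0 and g is pure noise.
2. **Higher simplices,** dimensions processed bottom-up. For each
   p-simplex α let γ_max be its facet of largest value. If γ_max has not
   yet been claimed by another cofacet, α is *paired* with it:
   f(α) = f(γ_max), and γ_max is flagged as claimed. Otherwise
   f(α) = f(γ_max) + ε with fresh noise from (0, 0.5). Paired simplices
   and claimed faces are never critical, so each successful pairing
   removes two simplices from the critical set.

Exact floating-point ties between facet values (measure zero but
possible) break toward the lexicographically smallest facet, keeping
runs deterministic.

### Traversal order within a dimension

The greedy pairing's quality depends on the order in which simplices of
one dimension are visited. Two conventions are provided:

* `"shuffled"` (default): a permutation drawn from the same seeded
  generator. This emulates traversal of an unordered container and is
  the convention under which the benchmark μ values for the five model
  families are calibrated; on clustered geometric graphs it leaves a
  visible excess of critical triangles and tetrahedra.
* `"lexicographic"`: a seed-independent sweep in sorted-tuple order.
  Because consecutive simplices share vertices, claims propagate locally
  and the matching comes out near-perfect (μ → 1) on clustered
  complexes. Scientifically this is the *better* Morse function, but it
  is not the convention the benchmark optimality profile reflects, so it
  is opt-in.

Both satisfy the discrete Morse condition on every tested input
(property-checked across all generator families), and both obey the
Morse inequalities m_p ≥ β_p and the Euler identity exactly.

### Randomness and reproducibility

One `numpy` generator per construction step: vertex noise is drawn in
sorted-vertex order, the per-dimension permutation and fallback noise in
processing order. `analyze_graph(seed=...)` derives independent child
seeds for the vertex function and the assignment via `SeedSequence`, so
every pipeline output is bit-reproducible from a single integer.

## Filtrations

The level subcomplex K(r) contains every simplex of weight ≤ r together
with its faces; a simplex's *entry value* is min f over its coface
closure (computed top-down in one pass). Three schemes:

* **full** — one step per distinct weight; fw(α) = entry(α).
* **critical** (default) — fw(α) is the smallest critical weight
  ≥ entry(α). Between consecutive critical weights the level
  subcomplexes are homotopy equivalent, so the diagram's
  nonzero-persistence points are unchanged; this is property-checked by
  snapping the full filtration's diagram to the critical grid and
  comparing multisets exactly. Entry values beyond the last critical
  weight are assigned the last critical weight: this completes K in the
  final step without creating or moving any nonzero-persistence point.
* **dimension** — fw(α) = dim(α), the classical baseline under which
  every simplex is critical (μ = 0); included for comparison.

Within equal fw, simplices are ordered by dimension then lexicographic
tuple, which guarantees faces precede cofaces as the reduction requires.
Birth/death weights are normalized by w_N = 1 + max f over all simplices
(computed on the Morse function, not the snapped weights), mapping
filtrations into [0, 1); for the dimension scheme the same formula gives
w_N = 1 + d. Essential classes are stored as death = +∞ and normalized
to exactly 1.

One sign convention: persistence is reported as death − birth (a
non-negative quantity under birth < death), and barcodes/diagrams use
normalized coordinates in the unit square.

## Persistence computation

Standard left-to-right column reduction of the sparse GF(2) boundary
matrix (Python sets, symmetric difference; no twist/clearing
optimizations — the complexes at benchmark scale have a few thousand
simplices and reduce in well under a second). Zero-persistence pairs are
dropped from diagrams; equal points merge with summed multiplicity.
Correctness is cross-checked in tests against an independent dense GF(2)
Gaussian-elimination pairing, rank–nullity Betti numbers, and a
union-find component count for β₀.

## Diagram distances

Bottleneck and q-Wasserstein distances operate on normalized
multiplicity-expanded points pooled across dimensions (per-dimension
variants available). Unequal cardinalities use the standard diagonal
augmentation: each side is padded with the other side's diagonal
projections at cost (death − birth)/2, and diagonal padding matches
diagonal padding at zero cost. The bottleneck is exact: binary search
over the finite candidate-cost set with a bipartite feasibility test at
each threshold; only points farther than the threshold from the diagonal
constrain the matching, and saturating both sides' constrained points
reduces (Mendelsohn–Dulmage) to two independent Hall checks, each a
small maximum bipartite matching. Wasserstein solves the augmented
min-cost assignment with the Hungarian algorithm. Both are verified in
tests against exhaustive enumeration over augmented bijections at small
size, along with symmetry, triangle inequality (tolerance 1e−9) and
W_∞ ≤ W_q.

## Model-network generators

The benchmark conditions are five families at n = 1000 vertices and
expected average degree 4; these are the generator defaults used by the
experiments:

* **ER(n, p)** — each of the C(n, 2) pairs is an edge independently with
  probability p; benchmark p = 0.004.
* **WS(n, k, p)** — ring lattice with k nearest neighbours (k even),
  each edge rewired with probability p to a uniform non-duplicating
  target (resampling), preserving exactly nk/2 edges; benchmark
  k = 4, p = 0.5.
* **BA(n, m)** — preferential attachment from m initially isolated seed
  vertices (the first arrival connects to all of them), m edges per
  arrival, giving exactly m(n − m) edges and a connected graph;
  benchmark m = 2.
* **Geometric, spherical (γ = ∞)** — n points uniform on the unit
  2-sphere, connected iff angular distance ≤ θ_R with
  (n − 1)(1 − cos θ_R)/2 = k; benchmark k = 4.
* **Geometric, hyperbolic (γ = 2, T = 0)** — n points on a hyperbolic
  disk of radius R (curvature ζ = 1): angles uniform, radial density
  ∝ sinh(αr) with α = (γ − 1)/2; hard-threshold connection at
  hyperbolic distance ≤ R (the T = 0 step-function limit). R is
  calibrated by bisection so the *ensemble* expected average degree is
  k (tolerance 1 %), using a fixed Monte-Carlo pair sample (4 × 10⁶
  pairs) shared across bisection iterates so the objective is monotone
  in R; the calibrated R is cached per (n, k, γ) and is independent of
  the graph seed. Note the γ = 2 family is extremely heavy-tailed:
  single instances fluctuate far around the ensemble mean degree, which
  is faithful to the model.

All generators emit simple graphs with zero-padded decimal labels (so
lexicographic and numeric order agree) and are bit-reproducible per
seed.

## What the experiments show — and what they do not

The benchmark experiments run on synthetic model networks only. They
validate the construction (Morse property, Morse inequalities, Euler
identities, filtration equivalence), the published per-family optimality
profile μ, and the qualitative separation of families by bottleneck
distance between whole-complex diagrams (scale-free vs random farther
apart than random vs small-world; spherical vs hyperbolic geometry
clearly separated). They do not exercise real-network artifacts —
degree correlations, community structure, measurement noise — so
passing them shows the machinery is correct and the model-scale
behaviour reproduces, not that any particular real network will show a
given barcode. Real networks are supported through the edge-list reader
(self-loops dropped, duplicate edges collapsed, isolated vertices via an
optional side file), at the user's own scale judgement: the boundary
reduction is worst-case cubic, and very dense clique complexes (large
n₂, n₃) are the practical limit.

## Problem sizes used by tests and the acceptance script

μ experiment: 5 families × 10 replicates at n = 1000 (matching the
benchmark protocol). Separation: 10 replicate diagrams per family, mean
bottleneck over the 100 cross-pairs per comparison. Morse-validity
sweep: 200 graphs, n ∈ {50, 100, 150, 200}, across all families.
Oracle-agreement checks run at deliberately small sizes (complexes with
≤ 60 simplices, diagrams with ≤ 3 points) where the exhaustive and dense
oracles are exact and fast.
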