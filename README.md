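# morseph

Persistent homology of unweighted, undirected networks via discrete Morse
theory.

Many real networks — protein–protein interaction maps, power grids, road
and communication networks — are unweighted, which rules out the usual
edge-weight threshold filtration for persistent homology. `morseph`
implements an alternative: it assigns weights to *all* simplices of the
clique complex of the graph (vertices, edges, triangles, tetrahedra, …)
through a discrete Morse function built from vertex degrees, and filters
the complex through the resulting *critical weights*. Because level
subcomplexes between consecutive critical weights are homotopy
equivalent, this reduced filtration loses no homological information
while typically using far fewer steps than the full weight sequence.

## The method

Given a simple graph G, build its clique complex K up to a dimension cap
(default 3). Assign vertex weights

    g(v) = deg_max − degree(v) + ε,   ε ~ Uniform(0, 0.5),

so important (high-degree) vertices enter the filtration first. Extend g
to every simplex bottom-up: a simplex whose largest-valued facet γ_max is
still unclaimed is *paired* with it, f(α) = f(γ_max); otherwise
f(α) = f(γ_max) + ε with fresh noise. The result f satisfies the discrete
Morse condition (|U_α| ≤ 1 and |V_α| ≤ 1 for every simplex α). Simplices
with U_α = V_α = ∅ are *critical*; their count m_p obeys the Morse
inequalities m_p ≥ β_p and the Euler identity
Σ(−1)ᵖ m_p = Σ(−1)ᵖ β_p = Σ(−1)ᵖ n_p. The optimality of a run is
summarized by

    μ = (Σ n_p − Σ m_p) / (Σ n_p − Σ β_p)  ∈ [0, 1],

with μ = 1 at the Betti-number lower bound and μ = 0 when every simplex
is critical (as under the dimension-function baseline).

Persistence is computed over GF(2) by standard boundary-matrix column
reduction on the critical-weight filtration; birth/death weights are
normalized by w_N = 1 + max f, with essential classes at death 1.
Diagrams are compared with exact bottleneck and q-Wasserstein distances
(diagonal-augmented bipartite matching).

## Worked example

```python
import morseph as mp

g = mp.generate_er(1000, 0.004, seed=42)       # sparse random graph
res = mp.analyze_graph(g, cap=3, seed=7)       # full pipeline
print("n_p   =", res.n_p)
print("m_p   =", res.m_p)
print("beta_p=", res.beta_p)
print("mu    = %.4f" % res.mu)
print("steps =", res.n_steps)
```

prints

```
n_p   = (1000, 1954, 9)
m_p   = (86, 1032, 1)
beta_p= (17, 962, 0)
mu    = 0.9294
steps = 1119
```

— the 1000-vertex graph has 1954 edges and 9 triangles; the Morse
function leaves 1119 critical simplices against the theoretical floor of
979 homology generators (17 components, 962 independent cycles), i.e.
μ ≈ 0.93, and the filtration needs 1119 steps instead of one per simplex.
The same pipeline is scriptable from the shell:

```
morseph generate --model er --n 1000 --p 0.004 --seed 42 -o er.tsv
morseph summary er.tsv --seed 7 -o summary.tsv
morseph persist er.tsv --seed 7 -o diagram.tsv --barcode barcode.tsv
morseph distance diagramA.tsv diagramB.tsv --metric bottleneck
```

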