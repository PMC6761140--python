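"""Bottleneck and q-Wasserstein distances between persistence diagrams.

Diagrams are compared as multisets of normalized (birth, death) points in
the unit square, essential deaths at 1.  Unequal cardinalities are
handled by the standard diagonal augmentation: each side is padded with
the diagonal projections of the other side's points (nearest diagonal
point under the sup-norm, at cost (death - birth)/2), and diagonal
padding points match each other at zero cost.

The bottleneck distance is exact: binary search over the finite set of
candidate costs with a maximum-bipartite-matching feasibility test at
each threshold.  The q-Wasserstein distance is a min-cost assignment on
the augmented bipartite problem (Hungarian algorithm).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .persistence import PersistenceDiagram

Point = tuple[float, float]


def _expanded_points(diagram) -> list[Point]:
    """Normalized multiplicity-expanded points; lists pass through as-is."""
    if isinstance(diagram, PersistenceDiagram):
        return diagram.normalized_points()
    return [(float(b), float(d)) for b, d in diagram]


def diagonal_cost(point: Point) -> float:
    """Sup-norm distance from a point to its nearest diagonal point."""
    b, d = point
    return abs(d - b) / 2.0


def supnorm(x: Point, y: Point) -> float:
    return max(abs(x[0] - y[0]), abs(x[1] - y[1]))


def _point_arrays(xs: list[Point], ys: list[Point]):
    """Vectorized sup-norm cost matrix and per-point diagonal costs."""
    X = np.asarray(xs, dtype=float).reshape(-1, 2)
    Y = np.asarray(ys, dtype=float).reshape(-1, 2)
    C = np.maximum(np.abs(X[:, 0, None] - Y[None, :, 0]),
                   np.abs(X[:, 1, None] - Y[None, :, 1]))
    dX = np.abs(X[:, 1] - X[:, 0]) / 2.0
    dY = np.abs(Y[:, 1] - Y[:, 0]) / 2.0
    return C, dX, dY


def _cost_matrix(xs: list[Point], ys: list[Point], power: float = 1.0
                 ) -> np.ndarray:
    """Augmented (nx+ny) x (ny+nx) cost matrix.

    Rows: X points then ny diagonal slots; columns: Y points then nx
    diagonal slots.  Any X point may use any diagonal slot (cost = its own
    diagonal projection), and diagonal-to-diagonal costs are 0.
    """
    nx, ny = len(xs), len(ys)
    C0, dX, dY = _point_arrays(xs, ys)
    C = np.zeros((nx + ny, ny + nx))
    C[:nx, :ny] = C0 ** power
    C[:nx, ny:] = (dX ** power)[:, None]
    C[nx:, :ny] = (dY ** power)[None, :]
    return C


def bottleneck_distance(X, Y) -> float:
    """Exact bottleneck distance between two diagrams.

    Accepts :class:`PersistenceDiagram` objects (compared on normalized
    coordinates, pooled over dimensions) or plain lists of (birth, death)
    pairs.

    Binary search over the finite candidate set of pairwise and diagonal
    costs.  Feasibility at threshold t only constrains the points farther
    than t from the diagonal (everything else can ride the diagonal for
    free), and a matching saturating the long points of both sides exists
    iff each side's long points alone can be saturated (Mendelsohn-Dulmage),
    so each test is two small Hall checks via maximum bipartite matching.
    """
    xs, ys = _expanded_points(X), _expanded_points(Y)
    nx, ny = len(xs), len(ys)
    if nx == 0 and ny == 0:
        return 0.0
    C, dX, dY = _point_arrays(xs, ys)
    candidates = np.unique(np.concatenate(
        [C.ravel(), dX, dY, np.zeros(1)]))

    def feasible(t: float) -> bool:
        xl = np.flatnonzero(dX > t)
        yl = np.flatnonzero(dY > t)
        if xl.size > ny or yl.size > nx:
            return False
        if xl.size:
            m = maximum_bipartite_matching(
                csr_matrix(C[xl, :] <= t), perm_type="column")
            if int((m >= 0).sum()) < xl.size:
                return False
        if yl.size:
            m = maximum_bipartite_matching(
                csr_matrix(C[:, yl].T <= t), perm_type="column")
            if int((m >= 0).sum()) < yl.size:
                return False
        return True

    lo, hi = 0, len(candidates) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if feasible(candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


def wasserstein_distance(X, Y, q: int = 1) -> float:
    """q-Wasserstein distance (sup-norm ground metric, q >= 1)."""
    if q < 1:
        raise ValueError("q must be >= 1")
    xs, ys = _expanded_points(X), _expanded_points(Y)
    if not xs and not ys:
        return 0.0
    C = _cost_matrix(xs, ys, power=float(q))
    rows, cols = linear_sum_assignment(C)
    return float(C[rows, cols].sum() ** (1.0 / q))


def brute_force_distance(X, Y, q=None) -> float:
    """Exhaustive search over augmented bijections (tiny diagrams only).

    ``q=None`` gives the bottleneck (max-cost) objective; an integer q
    gives the q-Wasserstein objective.  Used as an independent oracle.
    """
    xs, ys = _expanded_points(X), _expanded_points(Y)
    if not xs and not ys:
        return 0.0
    C = _cost_matrix(xs, ys, power=1.0)
    n = C.shape[0]
    if n > 8:
        raise ValueError("brute force limited to 8 augmented points")
    best = math.inf
    for perm in itertools.permutations(range(n)):
        costs = [C[i, perm[i]] for i in range(n)]
        val = (max(costs) if q is None
               else sum(c ** q for c in costs) ** (1.0 / q))
        best = min(best, val)
    return best


def _per_dim_split(diagram: PersistenceDiagram) -> dict[int, list[Point]]:
    return diagram.normalized_points(per_dim=True)


def diagram_distance(X: PersistenceDiagram, Y: PersistenceDiagram,
                     metric: str = "bottleneck", per_dim: bool = False):
    """Distance between diagrams, pooled across dimensions by default.

    ``metric`` is "bottleneck", "w1" or "w2".  With ``per_dim`` a dict of
    per-dimension distances is returned instead.
    """
    def dist(a, b):
        if metric == "bottleneck":
            return bottleneck_distance(a, b)
        if metric in ("w1", "w2"):
            return wasserstein_distance(a, b, q=int(metric[1]))
        raise ValueError(f"unknown metric {metric!r}")

    if not per_dim:
        return dist(X, Y)
    xs, ys = _per_dim_split(X), _per_dim_split(Y)
    return {p: dist(xs.get(p, []), ys.get(p, []))
            for p in sorted(set(xs) | set(ys))}


def model_distance_matrix(specs: dict, replicates: int, seed,
                          metric: str = "bottleneck",
                          cap: int = 3) -> dict:
    """Mean pairwise diagram distance between model-network families.

    For each named model spec, ``replicates`` graphs are generated and run
    through the full pipeline (clique complex, Morse function, critical
    filtration, diagram).  For each unordered pair of distinct models the
    mean and standard error of the distance over all replicate cross-pairs
    (replicates^2 of them) are reported; within a model, over the
    C(replicates, 2) unordered pairs.

    ``specs`` maps a model name to a zero-argument-free callable
    ``f(seed) -> Graph``.
    """
    from .pipeline import analyze_graph

    rng = np.random.SeedSequence(seed)
    names = list(specs)
    diagrams: dict[str, list[PersistenceDiagram]] = {}
    for name in names:
        child = rng.spawn(1)[0]
        seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in child.spawn(replicates)]
        diagrams[name] = [
            analyze_graph(specs[name](s), cap=cap, seed=s).diagram
            for s in seeds
        ]

    result: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in itertools.combinations_with_replacement(names, 2):
        if a == b:
            vals = [diagram_distance(x, y, metric=metric)
                    for x, y in itertools.combinations(diagrams[a], 2)]
        else:
            vals = [diagram_distance(x, y, metric=metric)
                    for x in diagrams[a] for y in diagrams[b]]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
        result[(a, b)] = (float(vals.mean()), float(se))
    return result
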