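"""Seeded model-network generators: ER, WS, BA and geometric (HGG) graphs.

ER, WS and BA delegate to networkx (G(n,p) with independent edges; ring
lattice with probability-p resampling rewiring that preserves the nk/2
edge count; preferential attachment growing from m initially isolated
vertices).  The hyperbolic/spherical geometric family is implemented
here: at temperature T = 0 the connection rule is a hard threshold on
distance, with the threshold calibrated so the expected average degree
equals k.

Vertex labels are zero-padded decimal strings so that lexicographic and
numeric order coincide, keeping downstream processing order stable.
"""

from __future__ import annotations

import functools
import math

import networkx as nx
import numpy as np

from .graphio import Graph, graph_from_edges

_FIXTURES = {
    # deterministic toy graphs for tests and examples
    "single": ([], ["a"]),
    "edge": ([("a", "b")], []),
    "P3": ([("a", "b"), ("b", "c")], []),
    "K3": ([("a", "b"), ("a", "c"), ("b", "c")], []),
    "C4": ([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")], []),
    # 9 vertices, 11 edges, two triangles, one surviving 1-cycle; the
    # degree-5 hub v7 carries a pendant v8
    "two_triangles": ([
        ("v0", "v1"), ("v1", "v2"), ("v2", "v3"), ("v3", "v4"),
        ("v2", "v4"), ("v4", "v7"), ("v5", "v6"), ("v6", "v7"),
        ("v5", "v7"), ("v7", "v0"), ("v7", "v8"),
    ], []),
}


def fixture_graph(name: str) -> Graph:
    """Small deterministic graphs by name (single, edge, P3, K3, C4, ...)."""
    try:
        edges, extra = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"known: {sorted(_FIXTURES)}") from None
    return graph_from_edges(edges, extra_vertices=extra)


def _label(i: int, n: int) -> str:
    width = len(str(n - 1)) if n > 1 else 1
    return str(i).zfill(width)


def _from_nx(G: nx.Graph, n: int) -> Graph:
    labels = {i: _label(i, n) for i in G.nodes}
    return graph_from_edges(
        [(labels[u], labels[v]) for u, v in G.edges()],
        extra_vertices=labels.values())


def generate_er(n: int, p: float, seed) -> Graph:
    """Erdos-Renyi G(n, p): each pair is an edge independently with prob p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return _from_nx(nx.fast_gnp_random_graph(n, p, seed=int(seed)), n)


def generate_ws(n: int, k: int, p: float, seed) -> Graph:
    """Watts-Strogatz ring lattice with probability-p rewiring.

    Each vertex starts joined to its k nearest ring neighbours (k even,
    k < n); each edge is rewired with probability p to a uniformly chosen
    vertex, resampling to avoid self-loops and duplicates, so the edge
    count stays exactly nk/2.
    """
    if k % 2 != 0:
        raise ValueError("k must be even")
    if not 0 < k < n:
        raise ValueError("require 0 < k < n")
    return _from_nx(nx.watts_strogatz_graph(n, k, p, seed=int(seed)), n)


def generate_ba(n: int, m: int, seed) -> Graph:
    """Barabasi-Albert preferential attachment with m edges per arrival.

    The seed graph is m isolated vertices; the first arrival connects to
    all of them, after which attachment is degree-proportional, so the
    final edge count is exactly m(n - m) and the graph is connected.
    """
    if not 1 <= m < n:
        raise ValueError("require 1 <= m < n")
    return _from_nx(nx.barabasi_albert_graph(n, m, seed=int(seed)), n)


# ---------------------------------------------------------------------------
# Geometric random graphs (hyperbolic disk / sphere), temperature T = 0


def _hyperbolic_radii(u: np.ndarray, alpha: float, R: float) -> np.ndarray:
    # inverse CDF of density ~ sinh(alpha r) on [0, R]
    return np.arccosh(1.0 + u * (np.cosh(alpha * R) - 1.0)) / alpha


def _hyperbolic_mean_degree(n: int, alpha: float, R: float,
                            u1, u2, dtheta) -> float:
    """Expected average degree at threshold R, via fixed MC pair samples."""
    r1 = _hyperbolic_radii(u1, alpha, R)
    r2 = _hyperbolic_radii(u2, alpha, R)
    cosh_d = (np.cosh(r1) * np.cosh(r2)
              - np.sinh(r1) * np.sinh(r2) * np.cos(dtheta))
    p_conn = float(np.mean(cosh_d <= np.cosh(R)))
    return (n - 1) * p_conn


@functools.lru_cache(maxsize=None)
def _calibrate_radius(n: int, k: float, gamma: float,
                      samples: int = 4_000_000) -> float:
    """Disk radius R with expected average degree k, by bisection.

    Uses common random numbers (one fixed Monte-Carlo pair sample reused
    across bisection iterates) so the degree estimate is monotone
    decreasing in R and bisection converges; tolerance 1% of k.  The
    calibration RNG stream is fixed and independent of graph seeds.
    """
    alpha = (gamma - 1.0) / 2.0
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=20_260_921, spawn_key=(n, int(round(k * 1000)))))
    u1 = rng.random(samples)
    u2 = rng.random(samples)
    dtheta = rng.uniform(0.0, 2 * np.pi, samples)
    dtheta = np.minimum(dtheta, 2 * np.pi - dtheta)

    # expected degree decreases as the disk radius R grows (sparser graph)
    lo, hi = 1e-3, 40.0
    if _hyperbolic_mean_degree(n, alpha, lo, u1, u2, dtheta) < k:
        raise ValueError(f"average degree k={k} infeasible for n={n}")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        deg = _hyperbolic_mean_degree(n, alpha, mid, u1, u2, dtheta)
        if deg > k:
            lo = mid
        else:
            hi = mid
        if abs(deg - k) <= 0.01 * k:
            return mid
    return 0.5 * (lo + hi)


def _generate_hyperbolic(n: int, k: float, gamma: float, seed) -> Graph:
    R = _calibrate_radius(n, float(k), float(gamma))
    alpha = (gamma - 1.0) / 2.0
    rng = np.random.default_rng(seed)
    r = _hyperbolic_radii(rng.random(n), alpha, R)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    cosh_r, sinh_r = np.cosh(r), np.sinh(r)
    cosh_d = (np.outer(cosh_r, cosh_r)
              - np.outer(sinh_r, sinh_r)
              * np.cos(theta[:, None] - theta[None, :]))
    iu, ju = np.triu_indices(n, k=1)
    connected = cosh_d[iu, ju] <= np.cosh(R)
    labels = [_label(i, n) for i in range(n)]
    edges = [(labels[i], labels[j])
             for i, j in zip(iu[connected], ju[connected])]
    return graph_from_edges(edges, extra_vertices=labels)


def _generate_spherical(n: int, k: float, seed,
                        theta_R: float | None = None) -> Graph:
    if theta_R is None:
        cos_t = 1.0 - 2.0 * k / (n - 1)
        if cos_t < -1.0:
            raise ValueError(f"average degree k={k} infeasible for n={n}")
        theta_R = math.acos(cos_t)
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    dots = pts @ pts.T
    iu, ju = np.triu_indices(n, k=1)
    connected = dots[iu, ju] >= math.cos(theta_R)
    labels = [_label(i, n) for i in range(n)]
    edges = [(labels[i], labels[j])
             for i, j in zip(iu[connected], ju[connected])]
    return graph_from_edges(edges, extra_vertices=labels)


def generate_hgg(n: int, k: float, gamma: float, T: float = 0.0,
                 seed=None, theta_R: float | None = None) -> Graph:
    """Geometric random graph on the hyperbolic disk (or sphere).

    For finite gamma >= 2: n points on a hyperbolic disk of radius R
    (angles uniform, radial density ~ sinh(alpha r), alpha = (gamma-1)/2,
    curvature zeta = 1), connected iff their hyperbolic distance <= R,
    with R calibrated so the expected average degree is k.  For
    gamma = inf: n points uniform on the unit 2-sphere, connected iff the
    angular distance <= theta_R with (n-1)(1 - cos theta_R)/2 = k.

    Only the hard-threshold limit T = 0 is supported.
    """
    if T != 0.0:
        raise ValueError("only T = 0 (hard threshold) is supported")
    if k <= 0:
        raise ValueError("k must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    if math.isinf(gamma):
        return _generate_spherical(n, k, seed, theta_R=theta_R)
    if gamma < 2:
        raise ValueError("gamma must be >= 2 (or inf)")
    return _generate_hyperbolic(n, k, gamma, seed)
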