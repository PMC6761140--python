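import itertools

import numpy as np
import pytest

import morseph as mp


@pytest.fixture(scope="session")
def small_er_graphs():
    """A pool of seeded sparse-to-moderate ER graphs for property sweeps."""
    graphs = []
    for seed in range(20):
        n = 10 + (seed % 4) * 10
        p = 0.05 + 0.05 * (seed % 3)
        graphs.append(mp.generate_er(n, p, seed))
    return graphs


# ---------------------------------------------------------------------------
# Independent oracles (deliberately different code paths from the package)


def brute_force_cliques(graph, cap):
    """All complete vertex subsets of size <= cap+1, by direct checking."""
    verts = list(graph.vertices)
    out = {p: set() for p in range(cap + 1)}
    for size in range(1, cap + 2):
        for combo in itertools.combinations(sorted(verts), size):
            if all(graph.has_edge(u, v)
                   for u, v in itertools.combinations(combo, 2)):
                out[size - 1].add(combo)
    return {p: s for p, s in out.items() if s}


def gf2_rank(M):
    """Rank of a 0/1 matrix over GF(2) by dense Gaussian elimination."""
    M = (np.asarray(M, dtype=np.uint8) % 2).copy()
    rank = 0
    rows, cols = M.shape
    for c in range(cols):
        piv = None
        for i in range(rank, rows):
            if M[i, c]:
                piv = i
                break
        if piv is None:
            continue
        M[[rank, piv]] = M[[piv, rank]]
        for i in range(rows):
            if i != rank and M[i, c]:
                M[i] ^= M[rank]
        rank += 1
    return rank


def boundary_dense(cx, p):
    """Dense GF(2) boundary matrix from dimension p to p-1."""
    M = np.zeros((len(cx.simplices[p - 1]), len(cx.simplices[p])),
                 dtype=np.uint8)
    for j, fids in enumerate(cx.facets[p]):
        for i in fids:
            M[i, j] = 1
    return M


def betti_rank_nullity(cx):
    """beta_p = n_p - rank d_p - rank d_{p+1} over GF(2)."""
    ranks = [0] + [gf2_rank(boundary_dense(cx, p))
                   for p in range(1, cx.dim + 1)] + [0]
    return tuple(len(cx.simplices[p]) - ranks[p] - ranks[p + 1]
                 for p in range(cx.dim + 1))


def union_find_components(graph):
    parent = {v: v for v in graph.vertices}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in graph.edges:
        u, v = tuple(e)
        parent[find(u)] = find(v)
    return len({find(v) for v in graph.vertices})


def dense_persistence_pairs(filtration):
    """Persistence pairing by dense GF(2) column elimination.

    Independent of the package's sparse-set reduction: works on a full
    numpy matrix with explicit low-index bookkeeping.
    """
    order = filtration.order()
    pos = {pi: k for k, pi in enumerate(order)}
    cx = filtration.complex
    n = len(order)
    M = np.zeros((n, n), dtype=np.uint8)
    for k, (p, i) in enumerate(order):
        if p > 0:
            for j in cx.facets[p][i]:
                M[pos[(p - 1, j)], k] = 1

    def low(col):
        nz = np.flatnonzero(M[:, col])
        return int(nz[-1]) if nz.size else -1

    low_owner = {}
    for j in range(n):
        lo = low(j)
        while lo >= 0 and lo in low_owner:
            M[:, j] ^= M[:, low_owner[lo]]
            lo = low(j)
        if lo >= 0:
            low_owner[lo] = j
    pairs = {j: lo for lo, j in low_owner.items()}
    essential = [k for k in range(n)
                 if k not in pairs and k not in low_owner]
    return order, pairs, essential
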