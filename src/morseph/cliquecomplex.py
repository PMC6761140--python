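"""Clique complex of a simple graph, capped at a maximum dimension.

The clique complex has one p-simplex for every (p+1)-vertex complete
subgraph.  Construction is by ordered extension: every (p+1)-clique is
generated exactly once from its lexicographically smallest p-face and a
common neighbour ordered above all current members, so the per-dimension
simplex lists are deterministic (lexicographic) with no duplicates.

Orientation is not stored; homology downstream is over GF(2), where it is
immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graphio import Graph

Simplex = tuple[str, ...]

DEFAULT_CAP = 3


@dataclass
class CliqueComplex:
    """Simplices per dimension with face/coface incidence.

    Attributes
    ----------
    simplices : list of lists
        ``simplices[p]`` is the lexicographically sorted list of p-simplices
        (each a strictly increasing tuple of vertex labels).
    facets : list of lists
        ``facets[p][i]`` holds the indices (into ``simplices[p-1]``) of the
        (p-1)-faces of ``simplices[p][i]``; empty tuple for p = 0.
    cofacets : list of lists
        Inverse map: indices into ``simplices[p+1]`` of the cofacets.
    cap : int
        Construction cap on the dimension.
    """

    simplices: list[list[Simplex]]
    facets: list[list[tuple[int, ...]]]
    cofacets: list[list[tuple[int, ...]]]
    cap: int

    @property
    def dim(self) -> int:
        """Maximum dimension with at least one simplex (-1 if empty)."""
        return len(self.simplices) - 1

    @property
    def n_p(self) -> tuple[int, ...]:
        """Per-dimension simplex counts (n_0, ..., n_d)."""
        return tuple(len(s) for s in self.simplices)

    @property
    def n_simplices(self) -> int:
        return sum(self.n_p)

    def index_of(self, simplex: Simplex) -> tuple[int, int]:
        """Return (dim, position) of ``simplex``; KeyError if absent."""
        p = len(simplex) - 1
        if 0 <= p <= self.dim:
            lst = self.simplices[p]
            lo = _bisect(lst, simplex)
            if lo < len(lst) and lst[lo] == simplex:
                return p, lo
        raise KeyError(simplex)

    def __contains__(self, simplex: Simplex) -> bool:
        try:
            self.index_of(simplex)
            return True
        except KeyError:
            return False

    def iter_simplices(self):
        """Yield (p, index, simplex) over all simplices, dimension-major."""
        for p, lst in enumerate(self.simplices):
            for i, s in enumerate(lst):
                yield p, i, s


def _bisect(lst, item):
    import bisect
    return bisect.bisect_left(lst, item)


def build_clique_complex(graph: Graph, cap: int = DEFAULT_CAP) -> CliqueComplex:
    """Enumerate all cliques of ``graph`` with at most ``cap``+1 vertices.

    Parameters
    ----------
    graph : Graph
        A simple graph.
    cap : int
        Maximum simplex dimension to include (default 3).
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    adj: dict[str, set[str]] = {v: set() for v in graph.vertices}
    for e in graph.edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)

    levels: list[list[Simplex]] = []
    verts = [(v,) for v in graph.vertices]  # already sorted
    if verts:
        levels.append(verts)
    prev = verts
    for p in range(1, cap + 1):
        nxt: list[Simplex] = []
        for clique in prev:
            # extension candidates: common neighbours above the last vertex
            common = adj[clique[0]]
            for v in clique[1:]:
                common = common & adj[v]
            last = clique[-1]
            for w in sorted(common):
                if w > last:
                    nxt.append(clique + (w,))
        if not nxt:
            break
        nxt.sort()
        levels.append(nxt)
        prev = nxt

    # incidence maps
    facets: list[list[tuple[int, ...]]] = []
    cofacets: list[list[tuple[int, ...]]] = []
    index_maps = [
        {s: i for i, s in enumerate(lst)} for lst in levels
    ]
    for p, lst in enumerate(levels):
        if p == 0:
            facets.append([() for _ in lst])
        else:
            below = index_maps[p - 1]
            facets.append([
                tuple(below[s[:k] + s[k + 1:]] for k in range(len(s)))
                for s in lst
            ])
    for p, lst in enumerate(levels):
        cof: list[list[int]] = [[] for _ in lst]
        if p + 1 < len(levels):
            for j, face_ids in enumerate(facets[p + 1]):
                for i in face_ids:
                    cof[i].append(j)
        cofacets.append([tuple(c) for c in cof])

    return CliqueComplex(levels, facets, cofacets, cap)
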