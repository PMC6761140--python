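"""Reading and writing simple graphs and persistence-diagram tables.

Graphs are unweighted, undirected and simple: self-loops are dropped on
ingest and duplicate edges (in either vertex order) are collapsed.  Vertex
labels are opaque strings; numeric labels are not coerced, so mixed label
styles found in real edge-list exports survive a round-trip unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping


class EdgeListParseError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


@dataclass(frozen=True)
class Graph:
    """A simple undirected graph with deterministic (sorted) vertex order.

    Attributes
    ----------
    vertices : tuple of str
        Sorted vertex labels.
    edges : frozenset of frozenset
        Unordered vertex-label pairs.
    """

    vertices: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    _degree: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        deg = {v: 0 for v in self.vertices}
        for e in self.edges:
            for v in e:
                deg[v] += 1
        object.__setattr__(self, "_degree", deg)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, v: str) -> int:
        return self._degree[v]

    @property
    def degrees(self) -> Mapping[str, int]:
        return dict(self._degree)

    @property
    def deg_max(self) -> int:
        return max(self._degree.values(), default=0)

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.edges

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.edges)


def graph_from_edges(pairs: Iterable[tuple[str, str]],
                     extra_vertices: Iterable[str] = ()) -> Graph:
    """Build a :class:`Graph` from (u, v) label pairs.

    Self-loops are dropped (their endpoint is still recorded as a vertex)
    and duplicates collapse.  ``extra_vertices`` adds isolated vertices,
    which a bare edge list cannot otherwise express.
    """
    vertices: set[str] = set(extra_vertices)
    edges: set[frozenset[str]] = set()
    for u, v in pairs:
        u, v = str(u), str(v)
        vertices.add(u)
        vertices.add(v)
        if u != v:
            edges.add(frozenset((u, v)))
    return Graph(tuple(sorted(vertices)), frozenset(edges))


def read_edgelist(path, vertex_file=None) -> Graph:
    """Read a whitespace-separated edge list (two labels per line).

    Lines starting with ``#`` and blank lines are skipped; tokens beyond
    the second are ignored.  A line with a single token raises
    :class:`EdgeListParseError` naming the line number.  ``vertex_file``
    optionally supplies one vertex label per line (for isolated vertices).
    """
    pairs: list[tuple[str, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected two vertex labels, "
                    f"got {len(tokens)}")
            pairs.append((tokens[0], tokens[1]))
    extra: list[str] = []
    if vertex_file is not None:
        with open(vertex_file, "rt", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    extra.append(line.split()[0])
    return graph_from_edges(pairs, extra_vertices=extra)


def write_edgelist(graph: Graph, path, header: str | None = None) -> None:
    """Write one ``u v`` line per edge, sorted, with optional '#' header."""
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for u, v in graph.sorted_edges():
            fh.write(f"{u} {v}\n")


# ---------------------------------------------------------------------------
# Persistence-diagram tables

_DIAGRAM_COLUMNS = ("dim", "birth", "death", "multiplicity")


def write_diagram(diagram, path, header: str | None = None) -> None:
    """Write a persistence diagram as TSV, rows sorted by (dim, birth, death).

    Essential deaths are written as ``inf``; the normalization constant is
    carried in a ``# w_N`` comment.  Round-trips losslessly through
    :func:`read_diagram`.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# w_N {diagram.w_N!r}\n")
        fh.write("\t".join(_DIAGRAM_COLUMNS) + "\n")
        for pt in sorted(diagram.points,
                         key=lambda p: (p.dim, p.birth, p.death)):
            fh.write(f"{pt.dim}\t{pt.birth!r}\t{pt.death!r}\t"
                     f"{pt.multiplicity}\n")


def read_diagram(path):
    """Read a TSV persistence diagram written by :func:`write_diagram`."""
    from .persistence import PersistenceDiagram, PersistencePoint

    points = []
    w_N = 1.0
    with open(path, "rt", encoding="utf-8") as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("# w_N "):
                w_N = float(line.split()[2])
                continue
            if not line or line.startswith("#"):
                continue
            if not saw_header:
                if tuple(line.split("\t")) != _DIAGRAM_COLUMNS:
                    raise ValueError(
                        f"{path}: line {lineno}: bad diagram header")
                saw_header = True
                continue
            dim_s, birth_s, death_s, mult_s = line.split("\t")
            points.append(PersistencePoint(
                dim=int(dim_s), birth=float(birth_s),
                death=float(death_s), multiplicity=int(mult_s)))
    return PersistenceDiagram.from_points(points, w_N=w_N)


def write_table(rows: list[dict], path, header: str | None = None) -> None:
    """Write a list of homogeneous dicts as a '#'-headered TSV table."""
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        if not rows:
            return
        cols = list(rows[0])
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
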