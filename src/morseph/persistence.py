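"""Persistent homology over GF(2) by boundary-matrix column reduction.

Simplices are laid out in filtration order (weight, then dimension, then
lexicographic tuple, so faces precede cofaces).  Each column holds the
row indices of its simplex's facets; columns are reduced left to right by
adding (symmetric difference, i.e. addition over GF(2)) the earlier
column sharing the same lowest one, until all lowest ones are distinct.
A reduced non-zero column j kills the class born with its lowest row i,
giving a (birth, death) = (fw(i), fw(j)) point in dimension dim(i);
columns that end up zero and are never anyone's lowest row are essential
classes with death = +infinity (normalized death 1).

Zero-persistence pairs (birth == death) are dropped from diagrams; equal
points merge with summed multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .filtration import Filtration


@dataclass(frozen=True, order=True)
class PersistencePoint:
    dim: int
    birth: float
    death: float  # may be math.inf for essential classes
    multiplicity: int = 1

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    """Multiset of (dim, birth, death) points with multiplicities."""

    points: list[PersistencePoint]
    w_N: float = 1.0

    @classmethod
    def from_points(cls, points, w_N: float = 1.0) -> "PersistenceDiagram":
        """Merge duplicates, drop zero-persistence points, sort."""
        merged: dict[tuple[int, float, float], int] = {}
        for pt in points:
            if pt.birth == pt.death:
                continue
            key = (pt.dim, pt.birth, pt.death)
            merged[key] = merged.get(key, 0) + pt.multiplicity
        out = [PersistencePoint(d, b, dth, m)
               for (d, b, dth), m in sorted(merged.items())]
        return cls(out, w_N)

    def in_dimension(self, p: int) -> list[PersistencePoint]:
        return [pt for pt in self.points if pt.dim == p]

    @property
    def max_dim(self) -> int:
        return max((pt.dim for pt in self.points), default=-1)

    def normalized_points(self, per_dim: bool = False):
        """Multiplicity-expanded (birth, death) pairs scaled by 1/w_N.

        Essential deaths map to exactly 1, the unit-square convention.
        Returns a flat list, or a dict keyed by dimension if ``per_dim``.
        """
        def norm(pt):
            b = pt.birth / self.w_N
            d = 1.0 if math.isinf(pt.death) else pt.death / self.w_N
            return (b, d)

        if per_dim:
            out: dict[int, list[tuple[float, float]]] = {}
            for pt in self.points:
                out.setdefault(pt.dim, []).extend(
                    [norm(pt)] * pt.multiplicity)
            return out
        return [xy for pt in self.points
                for xy in [norm(pt)] * pt.multiplicity]

    def as_multiset(self) -> dict[tuple[int, float, float], int]:
        return {(pt.dim, pt.birth, pt.death): pt.multiplicity
                for pt in self.points}


@dataclass
class BettiTable:
    beta_p: tuple[int, ...]

    def __getitem__(self, p: int) -> int:
        return self.beta_p[p] if p < len(self.beta_p) else 0

    @property
    def total(self) -> int:
        return sum(self.beta_p)


@dataclass
class BoundaryMatrix:
    """Sparse GF(2) boundary matrix in filtration order."""

    columns: list[set[int]]
    dims: np.ndarray  # dimension of the simplex behind each column
    weights: np.ndarray  # filtration weight per column

    @classmethod
    def from_filtration(cls, filtration: Filtration) -> "BoundaryMatrix":
        if not filtration.check_monotone():
            raise ValueError("filtration is not monotone: a face has larger "
                             "weight than its coface")
        order = filtration.order()
        pos = {pi: k for k, pi in enumerate(order)}
        cx = filtration.complex
        columns: list[set[int]] = []
        dims = np.empty(len(order), dtype=np.int64)
        weights = np.empty(len(order), dtype=float)
        for k, (p, i) in enumerate(order):
            dims[k] = p
            weights[k] = filtration.fw[p][i]
            if p == 0:
                columns.append(set())
            else:
                columns.append({pos[(p - 1, j)] for j in cx.facets[p][i]})
        return cls(columns, dims, weights)


def reduce(matrix: BoundaryMatrix) -> tuple[list[set[int]], dict[int, int]]:
    """Standard left-to-right reduction; returns (reduced columns, pairing).

    The pairing maps each death column j to the birth row i it kills.
    """
    columns = [set(c) for c in matrix.columns]
    low_to_col: dict[int, int] = {}
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            other = low_to_col.get(low)
            if other is None:
                low_to_col[low] = j
                break
            col ^= columns[other]
    pairing = {j: max(col) for j, col in enumerate(columns) if col}
    return columns, pairing


def persistence_diagram(filtration: Filtration) -> PersistenceDiagram:
    """Persistence diagram of a monotone filtration.

    Points carry raw filtration weights; ``w_N`` from the filtration is
    kept for normalized views.  Zero-persistence pairs are dropped and
    essential classes get death = +infinity.
    """
    matrix = BoundaryMatrix.from_filtration(filtration)
    _, pairing = reduce(matrix)
    dead_rows = set(pairing.values())
    points: list[PersistencePoint] = []
    for j, i in pairing.items():
        points.append(PersistencePoint(
            dim=int(matrix.dims[i]),
            birth=float(matrix.weights[i]),
            death=float(matrix.weights[j])))
    for k in range(len(matrix.columns)):
        if k not in pairing and k not in dead_rows:
            points.append(PersistencePoint(
                dim=int(matrix.dims[k]),
                birth=float(matrix.weights[k]),
                death=math.inf))
    return PersistenceDiagram.from_points(points, w_N=filtration.w_N)


def betti_numbers(source) -> BettiTable:
    """Betti numbers of the full complex: essential points per dimension.

    Accepts a :class:`PersistenceDiagram` or a :class:`Filtration` (which
    is then reduced).
    """
    diagram = source
    if isinstance(source, Filtration):
        diagram = persistence_diagram(source)
        d = source.complex.dim
    else:
        d = diagram.max_dim
    beta = [0] * (max(d, -1) + 1)
    for pt in diagram.points:
        if math.isinf(pt.death):
            beta[pt.dim] += pt.multiplicity
    return BettiTable(tuple(beta))


def persistent_betti(diagram: PersistenceDiagram, w_i: float,
                     w_j: float) -> tuple[int, ...]:
    """Per-dimension count of classes born by w_i and still alive after w_j."""
    if w_i > w_j:
        raise ValueError("require w_i <= w_j")
    d = diagram.max_dim
    out = [0] * (max(d, -1) + 1)
    for pt in diagram.points:
        if pt.birth <= w_i and pt.death > w_j:
            out[pt.dim] += pt.multiplicity
    return tuple(out)


def barcode(diagram: PersistenceDiagram) -> dict[int, list[tuple[float, float]]]:
    """Normalized intervals per dimension, multiplicity-expanded.

    Intervals are [birth/w_N, death/w_N] sorted by (birth, death);
    essential intervals end at exactly 1.
    """
    out = diagram.normalized_points(per_dim=True)
    for p in out:
        out[p].sort()
    return out
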