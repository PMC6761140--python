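"""Filtrations of a clique complex: critical-weight, full-weight, dimension.

A level subcomplex K(r) holds every simplex of weight <= r together with
all faces of such simplices.  A simplex alpha therefore first appears at
its *entry value*: the minimum weight over alpha and all simplices
containing it.  The full filtration steps through every distinct weight;
the reduced (critical) filtration steps only through the critical-weight
subsequence — between consecutive critical weights the level subcomplexes
are homotopy equivalent, so nothing of homological consequence is skipped.
Each entry value is snapped up to the smallest critical weight at or above
it; simplices entering beyond the last critical weight are assigned the
last critical weight, which completes K in the final step without adding
or moving any nonzero-persistence point.

The dimension filtration (f = dim, the baseline scheme in which every
simplex is critical) is included for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cliquecomplex import CliqueComplex, Simplex
from .morse import CriticalSet, MorseFunction


@dataclass
class Filtration:
    """Per-simplex filtration weights plus the normalization constant.

    ``fw[p][i]`` is the filtration weight of the i-th p-simplex; ``w_N``
    normalizes birth/death weights into [0, 1); ``scheme`` is one of
    "critical", "full", "dimension".
    """

    complex: CliqueComplex
    fw: list[np.ndarray]
    w_N: float
    scheme: str

    def order(self) -> list[tuple[int, int]]:
        """Total order on simplices: (fw, dim, lexicographic tuple).

        Faces always precede cofaces, as the reduction algorithm requires.
        """
        keyed = [
            (float(self.fw[p][i]), p, s)
            for p, lst in enumerate(self.complex.simplices)
            for i, s in enumerate(lst)
        ]
        keyed.sort()
        lookup = [
            {s: i for i, s in enumerate(lst)}
            for lst in self.complex.simplices
        ]
        return [(p, lookup[p][s]) for _, p, s in keyed]

    def weight_of(self, simplex: Simplex) -> float:
        p, i = self.complex.index_of(simplex)
        return float(self.fw[p][i])

    @property
    def n_steps(self) -> int:
        """Number of distinct filtration weights."""
        vals = np.concatenate([v for v in self.fw]) if self.fw else np.empty(0)
        return int(np.unique(vals).size)

    def check_monotone(self) -> bool:
        for p in range(1, self.complex.dim + 1):
            for i, face_ids in enumerate(self.complex.facets[p]):
                for j in face_ids:
                    if self.fw[p - 1][j] > self.fw[p][i]:
                        return False
        return True


def entry_values(complex: CliqueComplex, f: MorseFunction) -> list[np.ndarray]:
    """Entry value of every simplex: min f over its coface closure.

    Computed top-down: entry(alpha) = min(f(alpha), min over cofacets of
    their entry values).
    """
    d = complex.dim
    entry = [np.array(v, dtype=float, copy=True) for v in f.values]
    for p in range(d - 1, -1, -1):
        above = entry[p + 1]
        for i, cof in enumerate(complex.cofacets[p]):
            for j in cof:
                if above[j] < entry[p][i]:
                    entry[p][i] = above[j]
    return entry


def entry_value(complex: CliqueComplex, f: MorseFunction,
                alpha: Simplex) -> float:
    """Entry value of a single simplex (min f over its coface closure)."""
    p, i = complex.index_of(alpha)  # raises KeyError if absent
    return float(entry_values(complex, f)[p][i])


def _normalization(f: MorseFunction) -> float:
    return 1.0 + f.max_value


def full_filtration(complex: CliqueComplex, f: MorseFunction) -> Filtration:
    """Filtration through every distinct Morse weight: fw = entry value."""
    return Filtration(complex, entry_values(complex, f),
                      _normalization(f), "full")


def critical_filtration(complex: CliqueComplex, f: MorseFunction,
                        critical: CriticalSet) -> Filtration:
    """Reduced filtration indexed by the critical-weight subsequence.

    fw(alpha) is the smallest critical weight >= entry(alpha); entry
    values beyond the last critical weight snap down to the last critical
    weight (the level subcomplexes past it are homotopy equivalent to K).
    """
    cw = np.asarray(critical.critical_weights, dtype=float)
    if complex.dim < 0:
        return Filtration(complex, [], 1.0, "critical")
    if cw.size == 0:
        raise ValueError("critical weight sequence is empty")
    fw = []
    for arr in entry_values(complex, f):
        idx = np.searchsorted(cw, arr, side="left")
        idx[idx >= cw.size] = cw.size - 1
        fw.append(cw[idx])
    return Filtration(complex, fw, _normalization(f), "critical")


def snap_to_critical(values, critical_weights) -> np.ndarray:
    """Map each value to the smallest critical weight >= it (last one if none).

    Infinite values pass through unchanged.
    """
    cw = np.asarray(critical_weights, dtype=float)
    vals = np.asarray(values, dtype=float)
    out = vals.copy()
    finite = np.isfinite(vals)
    idx = np.searchsorted(cw, vals[finite], side="left")
    idx[idx >= cw.size] = cw.size - 1
    out[finite] = cw[idx]
    return out


def dimension_filtration(complex: CliqueComplex) -> Filtration:
    """Baseline: fw(alpha) = dim(alpha); every simplex is critical.

    Normalized with w_N = 1 + d, the same convention as the Morse schemes,
    so normalized weights lie in [0, 1).
    """
    fw = [np.full(len(lst), float(p))
          for p, lst in enumerate(complex.simplices)]
    return Filtration(complex, fw, float(max(complex.dim + 1, 1)), "dimension")
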