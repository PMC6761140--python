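"""End-to-end analysis: graph -> clique complex -> Morse function ->
critical-weight filtration -> persistence diagram, plus the summary
quantities (n_p, m_p, beta_p, mu) reported per network."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cliquecomplex import DEFAULT_CAP, CliqueComplex, build_clique_complex
from .filtration import (Filtration, critical_filtration,
                         dimension_filtration, full_filtration)
from .graphio import Graph
from .morse import (CriticalSet, MorseFunction, assign_morse_function,
                    find_critical, optimality_mu, vertex_function)
from .persistence import (BettiTable, PersistenceDiagram, betti_numbers,
                          persistence_diagram)


@dataclass
class AnalysisResult:
    graph: Graph
    complex: CliqueComplex
    morse: MorseFunction
    critical: CriticalSet
    filtration: Filtration
    diagram: PersistenceDiagram
    betti: BettiTable

    @property
    def n_p(self) -> tuple[int, ...]:
        return self.complex.n_p

    @property
    def m_p(self) -> tuple[int, ...]:
        return self.critical.m_p

    @property
    def beta_p(self) -> tuple[int, ...]:
        return self.betti.beta_p

    @property
    def mu(self) -> float:
        return optimality_mu(self.n_p, self.m_p, self.beta_p)

    @property
    def n_steps(self) -> int:
        return self.filtration.n_steps


def derive_seeds(seed, count: int) -> list[int]:
    """Independent child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(count)]


def analyze_graph(graph: Graph, cap: int = DEFAULT_CAP, seed=0,
                  scheme: str = "critical") -> AnalysisResult:
    """Run the whole pipeline on one graph.

    ``scheme`` selects the filtration: "critical" (default), "full", or
    "dimension" (the all-critical baseline; the Morse function is still
    built so that n_p/m_p/beta_p stay comparable, but the filtration and
    diagram come from the dimension function).
    """
    complex = build_clique_complex(graph, cap=cap)
    seed_g, seed_f = derive_seeds(seed, 2)
    g = vertex_function(graph, seed_g)
    morse = assign_morse_function(complex, g, seed_f)
    if scheme == "dimension":
        filtration = dimension_filtration(complex)
        critical = _dimension_critical(complex)
    else:
        critical = find_critical(complex, morse)
        if scheme == "critical":
            filtration = critical_filtration(complex, morse, critical)
        elif scheme == "full":
            filtration = full_filtration(complex, morse)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    diagram = persistence_diagram(filtration)
    betti = betti_numbers(diagram)
    # pad betti to the complex dimension
    beta = tuple(betti[p] for p in range(complex.dim + 1))
    return AnalysisResult(graph, complex, morse, critical, filtration,
                          diagram, BettiTable(beta))


def _dimension_critical(complex: CliqueComplex) -> CriticalSet:
    # under the dimension function every simplex is critical
    critical = [(p, i) for p, lst in enumerate(complex.simplices)
                for i in range(len(lst))]
    return CriticalSet(critical, complex.n_p,
                       np.arange(complex.dim + 1, dtype=float))
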