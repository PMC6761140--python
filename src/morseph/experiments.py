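"""Benchmark experiments on model networks.

The study conditions are five model families at n = 1000 vertices and
expected average degree 4: ER(p = 0.004), WS(k = 4, p = 0.5), BA(m = 2),
spherical geometric (gamma = inf, T = 0, k = 4) and hyperbolic geometric
(gamma = 2, T = 0, k = 4).  The mu experiment averages the optimality
indicator over 10 replicates per model; the separation experiment
compares persistence diagrams between families with the bottleneck
distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import partial
from typing import Callable

import numpy as np

from . import netgen
from .cliquecomplex import DEFAULT_CAP
from .diagramdist import model_distance_matrix
from .graphio import Graph
from .pipeline import analyze_graph

#: generator factories for the benchmark study conditions
MODEL_FAMILIES: dict[str, Callable[[int], Graph]] = {
    "er": partial(netgen.generate_er, 1000, 0.004),
    "ws": lambda seed: netgen.generate_ws(1000, 4, 0.5, seed),
    "ba": partial(netgen.generate_ba, 1000, 2),
    "sph": lambda seed: netgen.generate_hgg(1000, 4.0, math.inf, 0.0, seed),
    "hyp": lambda seed: netgen.generate_hgg(1000, 4.0, 2.0, 0.0, seed),
}

DEFAULT_REPLICATES = 10


@dataclass
class RunConfig:
    """Configuration for a single-network summary run."""

    graph: Graph
    cap: int = DEFAULT_CAP
    seed: int = 0
    scheme: str = "critical"


def run_summary(config: RunConfig) -> dict:
    """Per-dimension table (n_p, m_p, beta_p) plus mu and step count."""
    res = analyze_graph(config.graph, cap=config.cap, seed=config.seed,
                        scheme=config.scheme)
    rows = [
        {"p": p, "n_p": res.n_p[p], "m_p": res.m_p[p],
         "beta_p": res.beta_p[p]}
        for p in range(res.complex.dim + 1)
    ]
    return {"rows": rows, "mu": res.mu, "n_steps": res.n_steps,
            "result": res}


def run_mu_experiment(models: dict[str, Callable[[int], Graph]] | None = None,
                      replicates: int = DEFAULT_REPLICATES, seed: int = 0,
                      cap: int = DEFAULT_CAP,
                      scheme: str = "critical") -> dict[str, dict]:
    """Mean mu (+/- sample standard deviation) per model family.

    Per replicate: generate a graph, build the cap-dimensional clique
    complex, construct the Morse function, count critical simplices and
    Betti numbers, and evaluate mu; then aggregate across replicates.
    Returns per-model dicts with keys mean, std, values, results.
    """
    if models is None:
        models = MODEL_FAMILIES
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    out: dict[str, dict] = {}
    master = np.random.SeedSequence(seed)
    for name, child in zip(models, master.spawn(len(models))):
        seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in child.spawn(replicates)]
        results = [
            analyze_graph(models[name](s), cap=cap, seed=s, scheme=scheme)
            for s in seeds
        ]
        mus = np.array([r.mu for r in results])
        out[name] = {
            "mean": float(mus.mean()),
            "std": float(mus.std(ddof=1)),
            "values": mus.tolist(),
            "results": results,
        }
    return out


def run_separation_experiment(model_names=("er", "ws", "ba", "sph", "hyp"),
                              replicates: int = DEFAULT_REPLICATES,
                              seed: int = 0, metric: str = "bottleneck",
                              cap: int = DEFAULT_CAP) -> dict:
    """Mean pairwise diagram distance between the named model families."""
    specs = {name: MODEL_FAMILIES[name] for name in model_names}
    return model_distance_matrix(specs, replicates=replicates, seed=seed,
                                 metric=metric, cap=cap)
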