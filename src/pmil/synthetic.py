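"""Synthetic bipartite graph generation and probe-edge holdout.

The generator produces graphs spanning the regimes typical of published
drug-target and social affiliation networks: tens to thousands of nodes
per side, average degrees from near 1 to about 40, and either a flat or a
right-skewed (preferential-attachment style) degree distribution.
Isolated nodes are allowed by default — very sparse real networks have
them — but a spanning assignment can force minimum degree 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Set, Tuple

import numpy as np

from .graph import BipartiteGraph

__all__ = ["SynthConfig", "generate", "plant_probe"]

Pair = Tuple[str, str]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic bipartite graph.

    degree_model 'uniform' draws edges uniformly from U x V without
    replacement; 'preferential' grows the edge set by picking endpoints
    with probability proportional to (current degree + 1), yielding
    right-skewed degrees on both sides.
    """

    n_u: int
    n_v: int
    n_edges: int
    degree_model: str = "uniform"
    min_degree_one: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_u < 1 or self.n_v < 1:
            raise ValueError("both sides need at least one node")
        if not 0 <= self.n_edges <= self.n_u * self.n_v:
            raise ValueError(
                f"n_edges must lie in [0, {self.n_u * self.n_v}]"
            )
        if self.degree_model not in ("uniform", "preferential"):
            raise ValueError("degree_model must be 'uniform' or 'preferential'")
        if self.min_degree_one and self.n_edges < max(self.n_u, self.n_v):
            raise ValueError(
                "min_degree_one requires n_edges >= max(n_u, n_v)"
            )


def _node_names(prefix: str, n: int) -> List[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"{prefix}{idx:0{width}d}" for idx in range(n)]


def generate(config: SynthConfig) -> BipartiteGraph:
    """Generate a bipartite graph with exactly ``config.n_edges`` edges."""
    rng = np.random.default_rng(config.seed)
    u_names = _node_names("u", config.n_u)
    v_names = _node_names("v", config.n_v)
    chosen: Set[Tuple[int, int]] = set()

    if config.min_degree_one:
        # spanning assignment: cycle a random permutation of each side so
        # max(n_u, n_v) distinct edges cover every node at least once
        perm_u = rng.permutation(config.n_u)
        perm_v = rng.permutation(config.n_v)
        for k in range(max(config.n_u, config.n_v)):
            chosen.add(
                (int(perm_u[k % config.n_u]), int(perm_v[k % config.n_v]))
            )

    if config.degree_model == "uniform":
        total = config.n_u * config.n_v
        need = config.n_edges - len(chosen)
        while need > 0:
            flat = rng.choice(total, size=min(total, 2 * need + 8), replace=False)
            for f in flat:
                pair = (int(f) // config.n_v, int(f) % config.n_v)
                if pair not in chosen:
                    chosen.add(pair)
                    need -= 1
                    if need == 0:
                        break
    else:
        deg_u = np.ones(config.n_u)
        deg_v = np.ones(config.n_v)
        for i, j in chosen:
            deg_u[i] += 1
            deg_v[j] += 1
        attempts = 0
        max_attempts = 200 * (config.n_edges + 1) + 1000
        while len(chosen) < config.n_edges:
            i = int(rng.choice(config.n_u, p=deg_u / deg_u.sum()))
            j = int(rng.choice(config.n_v, p=deg_v / deg_v.sum()))
            attempts += 1
            if (i, j) not in chosen:
                chosen.add((i, j))
                deg_u[i] += 1
                deg_v[j] += 1
            elif attempts > max_attempts:
                # dense corner: fall back to a uniform draw over the
                # remaining non-edges to guarantee termination
                remaining = [
                    (a, b)
                    for a in range(config.n_u)
                    for b in range(config.n_v)
                    if (a, b) not in chosen
                ]
                idx = rng.choice(
                    len(remaining), size=config.n_edges - len(chosen),
                    replace=False,
                )
                for f in idx:
                    chosen.add(remaining[int(f)])
                break

    edges = sorted(chosen)
    g = BipartiteGraph(u_nodes=u_names, v_nodes=v_names)
    for i, j in edges:
        g.add_edge(u_names[i], v_names[j])
    return g


def plant_probe(
    g: BipartiteGraph, fraction: float, seed: int
) -> Tuple[BipartiteGraph, Set[Pair]]:
    """Split edges into a training graph and a held-out probe set.

    Removes ceil(fraction * |E|) edges uniformly at random.  The training
    graph keeps every node of ``g`` (also those left isolated), so
    candidate enumeration stays aligned with the original node sets.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    edges = sorted(g.edges)
    n_probe = math.ceil(fraction * len(edges))
    probe_idx = set(
        int(i) for i in rng.choice(len(edges), size=n_probe, replace=False)
    )
    probe = {edges[i] for i in probe_idx}
    train = BipartiteGraph(u_nodes=g.u_nodes, v_nodes=g.v_nodes)
    for k, (u, v) in enumerate(edges):
        if k not in probe_idx:
            train.add_edge(u, v)
    return train, probe
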