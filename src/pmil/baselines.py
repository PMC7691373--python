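"""Neighbour-based baseline predictors for cross-side candidate pairs.

The classical unipartite indices (common neighbours, Jaccard,
preferential attachment, cosine) do not apply verbatim to bipartite
graphs — a candidate pair (a, i) sits on opposite sides and never shares
direct neighbours.  Here they are adapted through the same geometry the
pattern-covered construction uses: the projected neighbourhood N_u(a) of
the U-side node is compared with the bipartite neighbourhood N(i) of the
V-side node, both subsets of U.  Preferential attachment uses plain
bipartite degrees.  This adaptation is this package's convention.
"""

from __future__ import annotations

import math
from typing import Callable

from .graph import BipartiteGraph, ProjectedGraph
from .pmis import PMISModel

__all__ = ["BASELINES", "baseline_score", "make_scorer", "METHODS"]

BASELINES = ("cn", "jc", "pa", "cs")
METHODS = ("pmil",) + BASELINES


def baseline_score(
    name: str, g: BipartiteGraph, pg: ProjectedGraph, a: str, i: str
) -> float:
    """Score candidate (a, i) with a named baseline.

    cn: |N_u(a) n N(i)|            jc: cn / |N_u(a) u N(i)|
    pa: |N(a)| * |N(i)|            cs: cn / sqrt(|N_u(a)| * |N(i)|)

    Empty neighbourhoods make jc and cs equal 0, never an error.
    """
    name = name.lower()
    if name == "pa":
        return float(g.degree(a) * g.degree(i))
    na = pg.neighbors(a)
    ni = g.neighbors(i)
    cn = len(na & ni)
    if name == "cn":
        return float(cn)
    if name == "jc":
        union = len(na | ni)
        return cn / union if union else 0.0
    if name == "cs":
        denom = math.sqrt(len(na) * len(ni))
        return cn / denom if denom else 0.0
    raise ValueError(f"unknown baseline {name!r}; expected one of {BASELINES}")


def make_scorer(
    method: str, g: BipartiteGraph, side: str = "u", **pmil_kwargs
) -> Callable[[str, str], float]:
    """Build a (side-node, other-node) -> score function for any method."""
    method = method.lower()
    if method == "pmil":
        model = PMISModel(g, side=side, **pmil_kwargs)
        return model.score
    if method in BASELINES:
        from .graph import project_weighted

        pg = project_weighted(g, side)
        return lambda a, i: baseline_score(method, g, pg, a, i)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
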