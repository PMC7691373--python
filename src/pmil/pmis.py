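"""Total pattern weights and the PMIS link-prediction score.

Every projected edge (pattern) {A, B} carries three weights — the
potential energy PE(A, B), the mutual-information score S^MI_AB and the
shared-neighbour count WP(A, B) — summed raw into the total pattern
weight

    W_t(A, B) = PE(A, B) + S^MI_AB + WP(A, B).

The PMIS score of a cross-side candidate pair (A, i) is the sum of W_t
over all patterns covered by (A, i); a higher PMIS means the edge is more
likely to appear.  The three components live on different scales (WP is
an integer >= 1, PE is small, S^MI is in bits and may be negative); they
are summed without normalisation and reported individually for
transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

from .graph import BipartiteGraph, ProjectedGraph, patterns_covered, project_weighted
from .mi import MIContext
from .pe import PEParams, potential_energy

__all__ = ["PatternWeight", "ScoreRow", "pattern_weights", "pmis_score",
           "rank_candidates", "PMISModel"]

Pattern = FrozenSet[str]


@dataclass(frozen=True)
class PatternWeight:
    """Per-pattern record of the three weights and their sum."""

    pair: Tuple[str, str]
    pe: float
    mi: float
    wp: int

    @property
    def total(self) -> float:
        return self.pe + self.mi + self.wp


@dataclass(frozen=True)
class ScoreRow:
    """One ranked candidate: the projected-side node, the opposite-side
    node, and its PMIS score."""

    side_node: str
    other_node: str
    score: float


def pattern_weights(
    g: BipartiteGraph,
    pg: ProjectedGraph,
    params: PEParams = PEParams(),
    ctx: Optional[MIContext] = None,
) -> Dict[Pattern, PatternWeight]:
    """One PatternWeight per projected edge.

    For a pattern the shortest distance is 1 (it is an edge), so its PE is
    simply degree product times clustering sum (or the no-common-neighbour
    constant).
    """
    if ctx is None:
        ctx = MIContext(pg)
    elif ctx.pg is not pg:
        raise ValueError("MI context was built on a different projection")
    weights: Dict[Pattern, PatternWeight] = {}
    for (a, b), wp in sorted(pg.weighted_edges.items()):
        weights[frozenset((a, b))] = PatternWeight(
            pair=(a, b),
            pe=potential_energy(pg, a, b, params),
            mi=ctx.mi_score(a, b),
            wp=wp,
        )
    return weights


def pmis_score(
    g: BipartiteGraph,
    pg: ProjectedGraph,
    weights: Dict[Pattern, PatternWeight],
    a: str,
    i: str,
) -> float:
    """PMIS(a, i) = sum of W_t over patterns covered by (a, i); 0 if none."""
    covered = patterns_covered(g, pg, a, i)
    return sum(weights[p].total for p in covered)


def rank_candidates(
    g: BipartiteGraph,
    pg: ProjectedGraph,
    weights: Dict[Pattern, PatternWeight],
    candidates: Optional[Iterable[Tuple[str, str]]] = None,
) -> List[ScoreRow]:
    """Score and rank cross-side candidate pairs by descending PMIS.

    Defaults to every non-edge of the bipartite graph (on the projected
    side x the opposite side).  Ties break by the canonical pair order so
    the ranking is total and deterministic.
    """
    if pg.side_label == "u":
        side_nodes, other_nodes = g.u_nodes, g.v_nodes
    else:
        side_nodes, other_nodes = g.v_nodes, g.u_nodes
    if candidates is None:
        pairs = [
            (a, i)
            for a in side_nodes
            for i in other_nodes
            if not _is_edge(g, pg.side_label, a, i)
        ]
    else:
        pairs = []
        for a, i in candidates:
            if _is_edge(g, pg.side_label, a, i):
                raise ValueError(f"candidate ({a!r}, {i!r}) is already an edge")
            pairs.append((a, i))
    rows = [
        ScoreRow(a, i, pmis_score(g, pg, weights, a, i)) for a, i in pairs
    ]
    rows.sort(key=lambda r: (-r.score, r.side_node, r.other_node))
    return rows


def _is_edge(g: BipartiteGraph, side_label: str, a: str, i: str) -> bool:
    return g.has_edge(a, i) if side_label == "u" else g.has_edge(i, a)


class PMISModel:
    """End-to-end PMIL pipeline bound to one bipartite graph.

    projection -> PE + MI per pattern -> total pattern weight -> PMIS.
    """

    def __init__(
        self,
        g: BipartiteGraph,
        side: str = "u",
        params: PEParams = PEParams(),
        log_base: float = 2.0,
        eps: float = 1e-10,
    ) -> None:
        self.g = g
        self.side = side
        self.pg = project_weighted(g, side)
        self.params = params
        if self.pg.n_edges > 0:
            self.ctx: Optional[MIContext] = MIContext(
                self.pg, log_base=log_base, eps=eps
            )
            self.weights = pattern_weights(g, self.pg, params, self.ctx)
        else:
            # degenerate graph without any shared neighbour: no patterns,
            # every PMIS score is 0
            self.ctx = None
            self.weights = {}

    def score(self, a: str, i: str) -> float:
        if not self.weights:
            return 0.0
        return pmis_score(self.g, self.pg, self.weights, a, i)

    def rank(
        self, candidates: Optional[Iterable[Tuple[str, str]]] = None
    ) -> List[ScoreRow]:
        return rank_candidates(self.g, self.pg, self.weights, candidates)
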