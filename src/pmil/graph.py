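"""Bipartite and one-mode projected graph containers.

A bipartite graph G(U, V, E) has two disjoint node sets with edges only
between sides.  Its weighted U-projection is the unipartite graph on U in
which two nodes are adjacent iff they share at least one V-neighbour; the
edge weight WP(A, B) = |Gamma(A) n Gamma(B)| counts those shared
neighbours.  Every projected edge is a *pattern*: same-side evidence that
links through the opposite side already co-occur.

Structural primitives (degrees, triangles, clustering coefficients,
shortest distances) are evaluated on the unweighted skeleton of the
projection; WP enters the method only as one additive term of the total
pattern weight.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

__all__ = [
    "BipartiteGraph",
    "ProjectedGraph",
    "ParseError",
    "BipartitenessError",
    "read_bipartite_edgelist",
    "project_weighted",
    "patterns_covered",
]

Pair = Tuple[str, str]


class ParseError(ValueError):
    """Raised for a malformed edge-list line."""


class BipartitenessError(ValueError):
    """Raised when a node identifier occurs on both sides of the graph."""


def _canon(a: str, b: str) -> Pair:
    """Canonical (lexicographically sorted) form of an unordered pair."""
    return (a, b) if a <= b else (b, a)


class BipartiteGraph:
    """Simple undirected bipartite graph with opaque string node ids.

    Node order is first-seen and preserved, so every downstream ranking is
    reproducible.  Duplicate edges collapse silently; intra-side edges and
    self-loops are rejected.
    """

    def __init__(
        self,
        edges: Iterable[Pair] = (),
        u_nodes: Iterable[str] = (),
        v_nodes: Iterable[str] = (),
    ) -> None:
        self._u_order: List[str] = []
        self._v_order: List[str] = []
        self._u_adj: Dict[str, Set[str]] = {}
        self._v_adj: Dict[str, Set[str]] = {}
        for u in u_nodes:
            self._add_node(u, "u")
        for v in v_nodes:
            self._add_node(v, "v")
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction -------------------------------------------------

    def _add_node(self, node: str, side: str) -> None:
        if side == "u":
            if node in self._v_adj:
                raise BipartitenessError(
                    f"node {node!r} already belongs to side V"
                )
            if node not in self._u_adj:
                self._u_adj[node] = set()
                self._u_order.append(node)
        else:
            if node in self._u_adj:
                raise BipartitenessError(
                    f"node {node!r} already belongs to side U"
                )
            if node not in self._v_adj:
                self._v_adj[node] = set()
                self._v_order.append(node)

    def add_edge(self, u: str, v: str) -> None:
        self._add_node(u, "u")
        self._add_node(v, "v")
        self._u_adj[u].add(v)
        self._v_adj[v].add(u)

    # -- queries ------------------------------------------------------

    @property
    def u_nodes(self) -> List[str]:
        return list(self._u_order)

    @property
    def v_nodes(self) -> List[str]:
        return list(self._v_order)

    @property
    def edges(self) -> Set[Pair]:
        return {(u, v) for u, nbrs in self._u_adj.items() for v in nbrs}

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._u_adj.values())

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._u_adj and v in self._u_adj[u]

    def side(self, node: str) -> str:
        if node in self._u_adj:
            return "u"
        if node in self._v_adj:
            return "v"
        raise KeyError(f"unknown node {node!r}")

    def neighbors(self, node: str) -> Set[str]:
        """Bipartite neighbourhood N(node), a set on the opposite side."""
        if node in self._u_adj:
            return set(self._u_adj[node])
        if node in self._v_adj:
            return set(self._v_adj[node])
        raise KeyError(f"unknown node {node!r}")

    def degree(self, node: str) -> int:
        return len(self.neighbors(node))

    def swap_sides(self) -> "BipartiteGraph":
        """The same graph with U and V exchanged (for V-side projection)."""
        g = BipartiteGraph(u_nodes=self._v_order, v_nodes=self._u_order)
        for u, v in sorted(self.edges):
            g.add_edge(v, u)
        return g

    def write_edgelist(self, path, delimiter: str = "\t") -> None:
        with open(path, "w") as fh:
            for u in self._u_order:
                for v in sorted(self._u_adj[u]):
                    fh.write(f"{u}{delimiter}{v}\n")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteGraph):
            return NotImplemented
        return (
            set(self._u_order) == set(other._u_order)
            and set(self._v_order) == set(other._v_order)
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return (
            f"BipartiteGraph(|U|={len(self._u_order)}, "
            f"|V|={len(self._v_order)}, |E|={self.n_edges})"
        )


class ProjectedGraph:
    """One-mode projection with integer shared-neighbour weights WP.

    Carries every node of the projected side, including isolated ones, so
    degrees and distances are defined for the whole side.  The unweighted
    skeleton backs all structural queries.
    """

    def __init__(self, nodes: Sequence[str], side_label: str = "u") -> None:
        self.side_label = side_label
        self._order: List[str] = list(nodes)
        self._g = nx.Graph()
        self._g.add_nodes_from(nodes)
        self._wp: Dict[Pair, int] = {}

    def add_edge(self, a: str, b: str, wp: int) -> None:
        if wp < 1:
            raise ValueError("projected edges require WP >= 1")
        self._g.add_edge(a, b)
        self._wp[_canon(a, b)] = int(wp)

    @property
    def nodes(self) -> List[str]:
        return list(self._order)

    @property
    def weighted_edges(self) -> Dict[Pair, int]:
        return dict(self._wp)

    @property
    def n_edges(self) -> int:
        return len(self._wp)

    def has_edge(self, a: str, b: str) -> bool:
        return _canon(a, b) in self._wp

    def weight(self, a: str, b: str) -> int:
        return self._wp[_canon(a, b)]

    def neighbors(self, node: str) -> Set[str]:
        """Projected-graph neighbourhood N_u(node) / Gamma(node)."""
        self._check(node)
        return set(self._g[node])

    def degree(self, node: str) -> int:
        self._check(node)
        return self._g.degree(node)

    def clustering_coefficient(self, z: str) -> float:
        """C_z = 2 t_z / (d_z (d_z - 1)) on the skeleton; 0 when d_z < 2."""
        self._check(z)
        return float(nx.clustering(self._g, z))

    def triangles(self, z: str) -> int:
        self._check(z)
        return int(nx.triangles(self._g, z))

    def shortest_distance(self, a: str, b: str) -> float:
        """Unweighted hop count; 0 iff a == b; math.inf when disconnected."""
        self._check(a)
        self._check(b)
        try:
            return float(nx.shortest_path_length(self._g, a, b))
        except nx.NetworkXNoPath:
            return math.inf

    def skeleton(self) -> nx.Graph:
        return self._g.copy()

    def write_edgelist(self, path, delimiter: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(f"# projected side: {self.side_label}\n")
            for (a, b), wp in sorted(self._wp.items()):
                fh.write(f"{a}{delimiter}{b}{delimiter}{wp}\n")

    def _check(self, node: str) -> None:
        if node not in self._g:
            raise KeyError(f"unknown node {node!r} in projected graph")

    def __repr__(self) -> str:
        return (
            f"ProjectedGraph(side={self.side_label!r}, "
            f"|nodes|={len(self._order)}, |edges|={self.n_edges})"
        )


def read_bipartite_edgelist(
    path, delimiter: Optional[str] = None
) -> BipartiteGraph:
    """Read a two-column edge list (column 1 = side U, column 2 = side V).

    Lines beginning with ``#`` are comments.  The delimiter is auto-detected
    between tab and comma (falling back to arbitrary whitespace) unless
    given.  Duplicate lines collapse; node order is first-seen.
    """
    g = BipartiteGraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is not None:
                fields = line.split(delimiter)
            elif "\t" in line:
                fields = line.split("\t")
            elif "," in line:
                fields = line.split(",")
            else:
                fields = line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least two fields, "
                    f"got {line!r}"
                )
            g.add_edge(fields[0], fields[1])
    return g


def project_weighted(g: BipartiteGraph, side: str = "u") -> ProjectedGraph:
    """Weighted one-mode projection onto ``side`` ('u' or 'v').

    Two same-side nodes are joined iff they share at least one bipartite
    neighbour; the edge weight is the shared-neighbour count.
    """
    if side not in ("u", "v"):
        raise ValueError("side must be 'u' or 'v'")
    work = g if side == "u" else g.swap_sides()
    pg = ProjectedGraph(work.u_nodes, side_label=side)
    counts: Dict[Pair, int] = {}
    for v in work.v_nodes:
        nbrs = sorted(work.neighbors(v))
        for a, b in itertools.combinations(nbrs, 2):
            key = _canon(a, b)
            counts[key] = counts.get(key, 0) + 1
    for (a, b), wp in sorted(counts.items()):
        pg.add_edge(a, b, wp)
    return pg


def patterns_covered(
    g: BipartiteGraph, pg: ProjectedGraph, a: str, i: str
) -> Set[FrozenSet[str]]:
    """Patterns {a, C} covered by the cross-side pair (a, i).

    C ranges over N_u(a) n N(i): projected neighbours of ``a`` that are
    also bipartite neighbours of ``i``.  Each returned pair is an edge of
    the projection, i.e. a pattern.
    """
    if g.side(a) != pg.side_label:
        raise ValueError(
            f"node {a!r} is not on the projected side {pg.side_label!r}"
        )
    if g.side(i) == pg.side_label:
        raise ValueError(f"node {i!r} must be on the opposite side")
    covered = pg.neighbors(a) & g.neighbors(i)
    return {frozenset((a, c)) for c in covered}
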