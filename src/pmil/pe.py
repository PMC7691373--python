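"""Graph-theoretic potential energy of a node pair.

By analogy with m*g*h: the degree product d_A * d_B plays the mass, the
sum of clustering coefficients of the pair's common neighbours plays the
gravitational constant, and the inverse shortest distance plays the
height:

    PE(A, B) = (d_A d_B) * (sum_{z in Gamma(A) n Gamma(B)} cl_z) * (1 / sd(A, B))

When the pair has no common neighbour the clustering sum is replaced by a
small positive constant (default 0.1) so that PE can still discriminate
such pairs through degrees and distance.  Disconnected pairs get PE = 0
by default (the continuous limit 1/sd -> 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .graph import ProjectedGraph

__all__ = ["PEParams", "potential_energy", "potential_energy_from_factors"]


@dataclass(frozen=True)
class PEParams:
    """Tunables of the potential-energy score.

    no_cn_constant:
        Stand-in for the clustering sum when the pair has no common
        neighbour; must be positive.
    disconnected_value:
        PE assigned to pairs in different components (where sd is
        infinite).
    """

    no_cn_constant: float = 0.1
    disconnected_value: float = 0.0

    def __post_init__(self) -> None:
        if self.no_cn_constant <= 0:
            raise ValueError("no_cn_constant must be > 0")


def potential_energy_from_factors(
    degree_product: float, clustering_sum: float, shortest_distance: float
) -> float:
    """PE from its three printed factors (degree product, cl-sum, sd)."""
    return degree_product * clustering_sum * (1.0 / shortest_distance)


def potential_energy(
    pg: ProjectedGraph, a: str, b: str, params: PEParams = PEParams()
) -> float:
    """PE(a, b) on the unweighted skeleton of the projected graph.

    Defined for every distinct pair, adjacent or not; symmetric and
    non-negative.
    """
    if a == b:
        raise ValueError("potential energy requires two distinct nodes")
    d_a = pg.degree(a)
    d_b = pg.degree(b)
    if d_a == 0 or d_b == 0:
        return 0.0
    sd = pg.shortest_distance(a, b)
    if math.isinf(sd):
        return params.disconnected_value
    common = pg.neighbors(a) & pg.neighbors(b)
    if common:
        cl_sum = sum(pg.clustering_coefficient(z) for z in common)
    else:
        cl_sum = params.no_cn_constant
    return potential_energy_from_factors(d_a * d_b, cl_sum, sd)
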