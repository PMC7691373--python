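"""Mutual-information likelihood score S^MI on the projected graph.

The score of a node pair (x, y) is the negative conditional
self-information of the link event L1_xy given the pair's common
neighbours O_xy:

    S^MI_xy = sum_{z in O_xy} I(L1; z) - I(L1_xy)

where I(L1; z) is the mean, over ordered neighbour pairs (m, n) of z, of
I(L1_mn) - I(L1_mn | z).  The unconditional link self-information comes
from a path-entropy estimate of the no-link probability,

    p(L0_mn) = C(T_l - d_m, d_n) / C(T_l, d_n),

with T_l the number of projected edges, and the conditional term from the
clustering coefficient of z, p(L1_mn | z) = C_z.  Higher S^MI means the
pair is more likely to be linked; the value can be negative.

All logarithms are base 2 (bits).  Probabilities are clamped into
[eps, 1] before taking logs so that zero clustering coefficients or
impossible links yield large-but-finite information instead of infinities;
the clamp preserves score ordering.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict

from scipy.special import gammaln

from .graph import ProjectedGraph

__all__ = ["MIContext", "prob_no_link", "self_info_link"]

#: probability floor applied before every logarithm
DEFAULT_EPS = 1e-10


def _log_binom(n: int, k: int) -> float:
    """log C(n, k); -inf when the coefficient is zero."""
    if k < 0 or k > n:
        return -math.inf
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def prob_no_link(total_edges: int, dm: int, dn: int) -> float:
    """p(L0) for a pair of degrees (dm, dn) in a graph of T_l edges.

    The path-entropy estimate C(T_l - dm, dn) / C(T_l, dn), evaluated via
    log-gamma so edge totals in the tens of thousands are safe.  Symmetric
    in (dm, dn); exactly 0 when dn > T_l - dm (the link is forced) and 1
    when either degree is 0.
    """
    if total_edges < 1:
        raise ValueError("total_edges must be >= 1")
    if dm < 0 or dn < 0:
        raise ValueError("degrees must be non-negative")
    if dm > total_edges or dn > total_edges:
        raise ValueError("degree exceeds total edge count")
    if dn == 0 or dm == 0:
        return 1.0
    log_num = _log_binom(total_edges - dm, dn)
    if log_num == -math.inf:
        return 0.0
    return float(math.exp(log_num - _log_binom(total_edges, dn)))


def self_info_link(
    total_edges: int,
    dm: int,
    dn: int,
    log_base: float = 2.0,
    eps: float = DEFAULT_EPS,
) -> float:
    """I(L1) = -log(1 - p(L0)), with the probability clamped to [eps, 1]."""
    p1 = 1.0 - prob_no_link(total_edges, dm, dn)
    return -math.log(min(max(p1, eps), 1.0)) / math.log(log_base)


class MIContext:
    """Cached mutual-information quantities for one projected graph.

    Parameters
    ----------
    pg:
        The projected (one-mode) graph; degrees, clustering coefficients
        and the edge total T_l are read from its unweighted skeleton.
    log_base:
        Base of every information quantity (default 2, i.e. bits).
    eps:
        Probability floor used before logarithms.
    """

    def __init__(
        self,
        pg: ProjectedGraph,
        log_base: float = 2.0,
        eps: float = DEFAULT_EPS,
    ) -> None:
        if pg.n_edges == 0:
            raise ValueError("projected graph has no edges; T_l must be > 0")
        self.pg = pg
        self.total_edges = pg.n_edges
        self.log_base = float(log_base)
        self.eps = float(eps)
        self._ln_base = math.log(self.log_base)
        self._per_node_mi: Dict[str, float] = {}

    # -- elementary quantities -----------------------------------------

    def _log(self, p: float) -> float:
        return math.log(min(max(p, self.eps), 1.0)) / self._ln_base

    def prob_no_link(self, dm: int, dn: int) -> float:
        """p(L0) for degrees (dm, dn) at this graph's T_l."""
        return prob_no_link(self.total_edges, dm, dn)

    def self_info_link(self, dm: int, dn: int) -> float:
        """I(L1) = -log p(L1) with p(L1) = 1 - p(L0), clamped."""
        return self_info_link(
            self.total_edges, dm, dn, log_base=self.log_base, eps=self.eps
        )

    def cond_self_info(self, z: str) -> float:
        """I(L1_mn | z) = -log C_z, the clustering-coefficient channel."""
        return -self._log(self.pg.clustering_coefficient(z))

    # -- per-node and pair scores --------------------------------------

    def node_mutual_info(self, z: str) -> float:
        """I(L1; z): mean link information gain over z's neighbour pairs.

        The normaliser |Gamma(z)|(|Gamma(z)| - 1) counts ordered pairs;
        every term is symmetric in (m, n), so the ordered mean equals the
        unordered one.  Undefined (raises) when z has fewer than two
        projected neighbours.
        """
        if z in self._per_node_mi:
            return self._per_node_mi[z]
        nbrs = sorted(self.pg.neighbors(z))
        k = len(nbrs)
        if k < 2:
            raise ValueError(
                f"node {z!r} has degree {k} < 2; I(L1; z) is undefined"
            )
        cond = self.cond_self_info(z)
        total = 0.0
        for m, n in itertools.combinations(nbrs, 2):
            total += self.self_info_link(self.pg.degree(m), self.pg.degree(n)) - cond
        value = 2.0 * total / (k * (k - 1))
        self._per_node_mi[z] = value
        return value

    def mi_score(self, x: str, y: str) -> float:
        """S^MI_xy = sum_{z in O_xy, d_z >= 2} I(L1; z) - I(L1_xy).

        Common neighbours of degree < 2 contribute nothing (their mean
        mutual information is undefined).  With no common neighbours the
        score reduces to -I(L1_xy).
        """
        if x == y:
            raise ValueError("mi_score requires two distinct nodes")
        common = self.pg.neighbors(x) & self.pg.neighbors(y)
        gain = sum(
            self.node_mutual_info(z) for z in sorted(common) if self.pg.degree(z) >= 2
        )
        return gain - self.self_info_link(self.pg.degree(x), self.pg.degree(y))
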