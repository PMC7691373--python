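"""Literal, unoptimised reference implementations used as test oracles.

Everything here is written directly from the defining formulas — plain
dict-of-sets adjacency, explicit product loops, BFS by hand, no caching —
and stays fully independent of the package's implementation so the two
routes can be compared.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

EPS = 1e-10


def clamp_log2(p: float) -> float:
    return math.log2(min(max(p, EPS), 1.0))


# -- plain-graph helpers (adjacency: dict node -> set of nodes) ---------

def bipartite_adj(edges):
    """(u_adj, v_adj) neighbour maps of a bipartite edge list."""
    u_adj, v_adj = {}, {}
    for u, v in edges:
        u_adj.setdefault(u, set()).add(v)
        v_adj.setdefault(v, set()).add(u)
    return u_adj, v_adj


def naive_projection(edges, side="u"):
    """Weighted projection by brute-force neighbour-set intersection."""
    u_adj, v_adj = bipartite_adj(edges)
    adj = u_adj if side == "u" else v_adj
    weights = {}
    for a, b in itertools.combinations(sorted(adj), 2):
        shared = len(adj[a] & adj[b])
        if shared:
            weights[tuple(sorted((a, b)))] = shared
    return weights


def proj_adj(weights):
    adj = {}
    for a, b in weights:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def naive_triangles(adj, z):
    nbrs = sorted(adj.get(z, set()))
    return sum(
        1 for m, n in itertools.combinations(nbrs, 2) if n in adj.get(m, set())
    )


def naive_clustering(adj, z):
    d = len(adj.get(z, set()))
    if d < 2:
        return 0.0
    return 2.0 * naive_triangles(adj, z) / (d * (d - 1))


def naive_sd(adj, a, b):
    if a == b:
        return 0
    seen = {a}
    queue = deque([(a, 0)])
    while queue:
        node, dist = queue.popleft()
        for nbr in adj.get(node, set()):
            if nbr == b:
                return dist + 1
            if nbr not in seen:
                seen.add(nbr)
                queue.append((nbr, dist + 1))
    return math.inf


# -- mutual information -------------------------------------------------

def naive_prob_no_link(tl, dm, dn):
    p = 1.0
    for i in range(1, dn + 1):
        num = tl - dm - i + 1
        den = tl - i + 1
        if num <= 0:
            return 0.0
        p *= num / den
    return p


def naive_self_info_link(tl, dm, dn):
    return -clamp_log2(1.0 - naive_prob_no_link(tl, dm, dn))


def naive_node_mi(adj, tl, z):
    """Mean over ordered neighbour pairs of I(L1_mn) - I(L1_mn | z)."""
    nbrs = sorted(adj[z])
    k = len(nbrs)
    assert k >= 2
    cond = -clamp_log2(naive_clustering(adj, z))
    total = 0.0
    for m in nbrs:
        for n in nbrs:
            if m == n:
                continue
            dm, dn = len(adj[m]), len(adj[n])
            total += naive_self_info_link(tl, dm, dn) - cond
    return total / (k * (k - 1))


def naive_mi_score(weights, x, y):
    adj = proj_adj(weights)
    tl = len(weights)
    common = adj.get(x, set()) & adj.get(y, set())
    gain = sum(
        naive_node_mi(adj, tl, z) for z in sorted(common) if len(adj[z]) >= 2
    )
    dx = len(adj.get(x, set()))
    dy = len(adj.get(y, set()))
    return gain - naive_self_info_link(tl, dx, dy)


# -- potential energy and PMIS -----------------------------------------

def naive_pe(weights, a, b, no_cn=0.1):
    adj = proj_adj(weights)
    da = len(adj.get(a, set()))
    db = len(adj.get(b, set()))
    if da == 0 or db == 0:
        return 0.0
    sd = naive_sd(adj, a, b)
    if math.isinf(sd):
        return 0.0
    common = adj[a] & adj[b]
    s = sum(naive_clustering(adj, z) for z in common) if common else no_cn
    return da * db * s * (1.0 / sd)


def naive_pattern_weight(weights, a, b, no_cn=0.1):
    key = tuple(sorted((a, b)))
    return (
        naive_pe(weights, a, b, no_cn)
        + naive_mi_score(weights, a, b)
        + weights[key]
    )


def naive_pmis(edges, a, i, side="u", no_cn=0.1):
    """PMIS by direct summation over patterns covered by (a, i)."""
    u_adj, v_adj = bipartite_adj(edges)
    bip = v_adj if side == "u" else u_adj  # neighbours of the i-side node
    weights = naive_projection(edges, side)
    adj = proj_adj(weights)
    covered = adj.get(a, set()) & bip.get(i, set())
    return sum(naive_pattern_weight(weights, a, c, no_cn) for c in covered)
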