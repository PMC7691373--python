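import numpy as np

from pmil import BipartiteGraph


def random_bipartite(n_u, n_v, n_edges, seed):
    """Uniform random bipartite graph as (BipartiteGraph, edge list)."""
    rng = np.random.default_rng(seed)
    all_pairs = [
        (f"u{i}", f"v{j}") for i in range(n_u) for j in range(n_v)
    ]
    idx = rng.choice(len(all_pairs), size=n_edges, replace=False)
    edges = [all_pairs[int(k)] for k in sorted(idx)]
    g = BipartiteGraph(
        edges,
        u_nodes=[f"u{i}" for i in range(n_u)],
        v_nodes=[f"v{j}" for j in range(n_v)],
    )
    return g, edges
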