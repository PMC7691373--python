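"""Edge-holdout evaluation: K-fold splits and ranking metrics.

A K-fold split partitions the bipartite edge set; each fold in turn is
the probe set E^p and the remaining K-1 folds form the training graph.
Four metrics quantify a predictor:

* AUC, in its sampling form: over N^t random (probe link, nonexistent
  link) comparisons, (N^h + 0.5 N^s) / N^t where N^h counts wins of the
  probe link and N^s ties.  Nonexistent links are cross-side pairs absent
  from both training and probe sets.
* Precision: the fraction of the top-L ranked candidates that are probe
  links; by default L equals the probe-set size.
* Prediction power: log10 of precision over a random predictor's
  expected precision L / (|U||V| - (E - L)), with E the training edge
  count.
* Precision@K for K in {10, 20, 50}.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .baselines import make_scorer
from .graph import BipartiteGraph

__all__ = [
    "SplitPlan",
    "EvalReport",
    "kfold_split",
    "training_graph",
    "auc_sampling",
    "exact_rank_auc",
    "precision_at_L",
    "prediction_power",
    "evaluate_fold",
    "cross_validate",
    "mean_report",
]

Pair = Tuple[str, str]
DEFAULT_PRECISION_AT = (10, 20, 50)


@dataclass(frozen=True)
class SplitPlan:
    """Assignment of every edge to one of k folds."""

    k: int
    fold_assignments: Dict[Pair, int]
    seed: int

    def fold_edges(self, fold: int) -> Set[Pair]:
        return {e for e, f in self.fold_assignments.items() if f == fold}


@dataclass
class EvalReport:
    """Metrics of one predictor on one split (or a mean over folds)."""

    method: str
    auc: float
    precision: float
    prediction_power: float
    precision_at: Dict[int, float]
    n_comparisons: int
    fold: Optional[int] = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "auc": self.auc,
            "precision": self.precision,
            "prediction_power": self.prediction_power,
            "n_comparisons": self.n_comparisons,
            "fold": self.fold,
        }
        for k, v in sorted(self.precision_at.items()):
            d[f"precision_at_{k}"] = v
        return d


def kfold_split(g: BipartiteGraph, k: int, seed: int) -> SplitPlan:
    """Uniform random partition of edges into k folds of near-equal size."""
    edges = sorted(g.edges)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(edges):
        raise ValueError(f"k={k} exceeds the edge count {len(edges)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    assignments = {edges[int(idx)]: pos % k for pos, idx in enumerate(order)}
    return SplitPlan(k=k, fold_assignments=assignments, seed=seed)


def training_graph(g: BipartiteGraph, probe: Set[Pair]) -> BipartiteGraph:
    """The graph with probe edges removed; node sets preserved."""
    train = BipartiteGraph(u_nodes=g.u_nodes, v_nodes=g.v_nodes)
    for u, v in sorted(g.edges):
        if (u, v) not in probe:
            train.add_edge(u, v)
    return train


def auc_sampling(
    scores_probe: Sequence[float],
    scores_nonexistent: Sequence[float],
    n_comparisons: int,
    seed: int,
) -> float:
    """Sampling AUC: (N^h + 0.5 N^s) / N^t over random score comparisons."""
    if len(scores_probe) == 0 or len(scores_nonexistent) == 0:
        raise ValueError("both score lists must be non-empty")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    rng = np.random.default_rng(seed)
    probe = np.asarray(scores_probe, dtype=float)
    nonex = np.asarray(scores_nonexistent, dtype=float)
    p = probe[rng.integers(len(probe), size=n_comparisons)]
    q = nonex[rng.integers(len(nonex), size=n_comparisons)]
    n_higher = int(np.sum(p > q))
    n_same = int(np.sum(p == q))
    return (n_higher + 0.5 * n_same) / n_comparisons


def exact_rank_auc(
    scores_probe: Sequence[float], scores_nonexistent: Sequence[float]
) -> float:
    """Exact AUC by full pair enumeration (Mann-Whitney form)."""
    probe = np.asarray(scores_probe, dtype=float)
    nonex = np.asarray(scores_nonexistent, dtype=float)
    wins = np.sum(probe[:, None] > nonex[None, :])
    ties = np.sum(probe[:, None] == nonex[None, :])
    return float((wins + 0.5 * ties) / (len(probe) * len(nonex)))


def precision_at_L(
    ranked: Sequence[Tuple[str, str]], probe_edges: Set[Pair], L: int
) -> float:
    """Fraction of the top-L ranked pairs that are probe links."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if not ranked:
        return 0.0
    top = ranked[: min(L, len(ranked))]
    hits = sum(1 for pair in top if pair in probe_edges)
    return hits / min(L, len(ranked))


def prediction_power(
    precision_method: float, g_train: BipartiteGraph, L: int
) -> float:
    """log10 ratio of a method's precision to the random predictor's.

    The random predictor's precision is L / (|U||V| - (E - L)) with E the
    training edge count; zero method precision maps to -inf.
    """
    n_u = len(g_train.u_nodes)
    n_v = len(g_train.v_nodes)
    denom = n_u * n_v - (g_train.n_edges - L)
    if denom <= 0:
        raise ValueError("degenerate random-precision denominator")
    p_random = L / denom
    if precision_method < 0:
        raise ValueError("precision must be >= 0")
    if precision_method == 0:
        return -math.inf
    return math.log10(precision_method / p_random)


def _candidate_pairs(
    g_full: BipartiteGraph, g_train: BipartiteGraph, side: str
) -> List[Pair]:
    """All cross-side pairs absent from the training graph (probe included)."""
    pairs = []
    for u in g_full.u_nodes:
        for v in g_full.v_nodes:
            if not g_train.has_edge(u, v):
                pairs.append((u, v))
    return pairs


def evaluate_fold(
    g_full: BipartiteGraph,
    g_train: BipartiteGraph,
    probe: Set[Pair],
    method: str = "pmil",
    side: str = "u",
    n_comparisons: int = 10_000,
    L: Optional[int] = None,
    precision_at: Sequence[int] = DEFAULT_PRECISION_AT,
    seed: int = 0,
    fold: Optional[int] = None,
    **scorer_kwargs,
) -> EvalReport:
    """Score all non-training pairs with one predictor and compute metrics.

    Candidates are every U x V pair absent from the training graph, so
    probe links compete against genuinely nonexistent ones.
    """
    scorer = make_scorer(method, g_train, side=side, **scorer_kwargs)

    def call(u: str, v: str) -> float:
        return scorer(u, v) if side == "u" else scorer(v, u)

    candidates = _candidate_pairs(g_full, g_train, side)
    scores = {pair: call(*pair) for pair in candidates}
    probe_scores = [scores[p] for p in sorted(probe)]
    nonexistent = [p for p in candidates if p not in probe]
    nonexistent_scores = [scores[p] for p in nonexistent]
    auc = auc_sampling(probe_scores, nonexistent_scores, n_comparisons, seed)

    ranked = sorted(candidates, key=lambda p: (-scores[p], p))
    L_eff = len(probe) if L is None else L
    precision = precision_at_L(ranked, probe, L_eff)
    pp = prediction_power(precision, g_train, L_eff)
    p_at = {k: precision_at_L(ranked, probe, k) for k in precision_at}
    return EvalReport(
        method=method,
        auc=auc,
        precision=precision,
        prediction_power=pp,
        precision_at=p_at,
        n_comparisons=n_comparisons,
        fold=fold,
    )


def cross_validate(
    g: BipartiteGraph,
    method: str = "pmil",
    k: int = 10,
    repeats: int = 1,
    side: str = "u",
    n_comparisons: int = 10_000,
    L: Optional[int] = None,
    precision_at: Sequence[int] = DEFAULT_PRECISION_AT,
    seed: int = 0,
    **scorer_kwargs,
) -> List[EvalReport]:
    """K-fold cross-validation, optionally repeated with fresh splits.

    Returns one report per (repeat, fold); summarise with
    :func:`mean_report`.
    """
    reports: List[EvalReport] = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(repeats)
    for r, child in enumerate(children):
        split_seed, auc_seed = (
            int(s) % (2**31) for s in child.generate_state(2)
        )
        plan = kfold_split(g, k, split_seed)
        for fold in range(k):
            probe = plan.fold_edges(fold)
            train = training_graph(g, probe)
            reports.append(
                evaluate_fold(
                    g,
                    train,
                    probe,
                    method=method,
                    side=side,
                    n_comparisons=n_comparisons,
                    L=L,
                    precision_at=precision_at,
                    seed=(auc_seed + fold) % (2**31),
                    fold=r * k + fold,
                    **scorer_kwargs,
                )
            )
    return reports


def mean_report(reports: Sequence[EvalReport]) -> EvalReport:
    """Arithmetic mean of per-fold metrics."""
    if not reports:
        raise ValueError("no reports to average")
    ks = sorted(reports[0].precision_at)
    return EvalReport(
        method=reports[0].method,
        auc=float(np.mean([r.auc for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        prediction_power=float(np.mean([r.prediction_power for r in reports])),
        precision_at={
            k: float(np.mean([r.precision_at[k] for r in reports])) for k in ks
        },
        n_comparisons=reports[0].n_comparisons,
        fold=None,
    )
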