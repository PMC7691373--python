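import math

import numpy as np
import pytest

from pmil import (
    BipartiteGraph,
    SynthConfig,
    auc_sampling,
    cross_validate,
    evaluate_fold,
    exact_rank_auc,
    generate,
    kfold_split,
    mean_report,
    plant_probe,
    precision_at_L,
    prediction_power,
    training_graph,
)


@pytest.fixture
def graph_100_edges():
    return generate(SynthConfig(n_u=15, n_v=15, n_edges=100, seed=3))


class TestKFoldSplit:
    def test_partition_into_equal_folds(self, graph_100_edges):
        plan = kfold_split(graph_100_edges, 10, seed=1)
        folds = [plan.fold_edges(f) for f in range(10)]
        assert all(len(f) == 10 for f in folds)
        union = set().union(*folds)
        assert union == graph_100_edges.edges
        assert sum(len(f) for f in folds) == 100

    def test_fold_sizes_differ_at_most_one(self, graph_100_edges):
        plan = kfold_split(graph_100_edges, 7, seed=1)
        sizes = [len(plan.fold_edges(f)) for f in range(7)]
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_same_plan(self, graph_100_edges):
        a = kfold_split(graph_100_edges, 10, seed=5)
        b = kfold_split(graph_100_edges, 10, seed=5)
        assert a.fold_assignments == b.fold_assignments

    def test_k_larger_than_edge_count_rejected(self):
        g = BipartiteGraph([("A", "x"), ("B", "y")])
        with pytest.raises(ValueError):
            kfold_split(g, 3, seed=0)

    def test_training_graph_drops_probe_keeps_nodes(self, graph_100_edges):
        plan = kfold_split(graph_100_edges, 10, seed=2)
        probe = plan.fold_edges(0)
        train = training_graph(graph_100_edges, probe)
        assert train.n_edges == 90
        assert train.u_nodes == graph_100_edges.u_nodes
        assert train.v_nodes == graph_100_edges.v_nodes
        assert not (train.edges & probe)


class TestAUCSampling:
    def test_perfect_separation_gives_one(self):
        auc = auc_sampling([2.0, 3.0, 4.0], [0.0, 1.0], 5000, seed=0)
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        auc = auc_sampling([1.0] * 5, [1.0] * 7, 5000, seed=0)
        assert auc == 0.5

    def test_within_three_se_of_exact_rank_auc(self):
        probe = [0.9, 0.5, 0.3]
        nonex = [0.8, 0.4, 0.1]
        exact = exact_rank_auc(probe, nonex)
        # per-draw outcome distribution from exhaustive pair enumeration
        outcomes = [
            1.0 if p > q else 0.5 if p == q else 0.0
            for p in probe for q in nonex
        ]
        var = float(np.var(outcomes))
        n = 100_000
        sampled = auc_sampling(probe, nonex, n, seed=42)
        assert abs(sampled - exact) <= 3 * math.sqrt(var / n)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            auc_sampling([], [1.0], 10, seed=0)
        with pytest.raises(ValueError):
            auc_sampling([1.0], [1.0], 0, seed=0)

    def test_exact_rank_auc_mann_whitney(self):
        # 3 wins + 1 tie*0.5 out of 4 comparisons
        assert exact_rank_auc([2.0, 1.0], [1.0, 0.0]) == pytest.approx(
            (3 + 0.5 * 1) / 4
        )


class TestPrecision:
    def test_all_hits(self):
        ranked = [("a", "x"), ("b", "y")]
        assert precision_at_L(ranked, {("a", "x"), ("b", "y")}, 2) == 1.0

    def test_no_hits(self):
        assert precision_at_L([("a", "x")], {("b", "y")}, 1) == 0.0

    def test_three_of_four(self):
        ranked = [("a", "1"), ("a", "2"), ("a", "3"), ("a", "4"), ("a", "5")]
        probe = {("a", "1"), ("a", "2"), ("a", "4")}
        assert precision_at_L(ranked, probe, 4) == 0.75

    def test_short_ranking_uses_all_rows(self):
        ranked = [("a", "1"), ("a", "2")]
        assert precision_at_L(ranked, {("a", "1")}, 10) == 0.5

    def test_empty_ranking_is_zero(self):
        assert precision_at_L([], {("a", "1")}, 5) == 0.0


class TestPredictionPower:
    def _graph(self, n_u, n_v, n_edges):
        return generate(SynthConfig(n_u=n_u, n_v=n_v, n_edges=n_edges, seed=0))

    def test_equal_to_random_is_zero(self):
        g = self._graph(10, 10, 40)
        p_random = 5 / (100 - (40 - 5))
        assert prediction_power(p_random, g, 5) == pytest.approx(0.0)

    def test_tenfold_random_is_one(self):
        g = self._graph(10, 10, 40)
        p_random = 5 / (100 - (40 - 5))
        assert prediction_power(10 * p_random, g, 5) == pytest.approx(1.0)

    def test_formula_value(self):
        # |U|=|V|=10, E=40, L=5: p_random = 5/65; PP(0.3) ~ 0.591
        g = self._graph(10, 10, 40)
        assert prediction_power(0.3, g, 5) == pytest.approx(
            math.log10(0.3 / (5 / 65)), rel=1e-12
        )
        assert prediction_power(0.3, g, 5) == pytest.approx(0.591, abs=1e-3)

    def test_zero_precision_maps_to_neg_inf(self):
        g = self._graph(10, 10, 40)
        assert prediction_power(0.0, g, 5) == -math.inf


class TestHarness:
    def test_random_scorer_auc_near_half(self):
        """Averaged over many random scorings, sampling AUC sits at 0.5."""
        g = generate(SynthConfig(n_u=20, n_v=20, n_edges=120, seed=9))
        train, probe = plant_probe(g, 0.1, seed=9)
        candidates = [
            (u, v)
            for u in g.u_nodes
            for v in g.v_nodes
            if not train.has_edge(u, v)
        ]
        nonex = [p for p in candidates if p not in probe]
        rng = np.random.default_rng(123)
        aucs = []
        for _ in range(100):
            scores = {p: rng.random() for p in candidates}
            aucs.append(
                auc_sampling(
                    [scores[p] for p in probe],
                    [scores[p] for p in nonex],
                    1000,
                    seed=int(rng.integers(2**31)),
                )
            )
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_evaluate_fold_reports_all_metrics(self):
        g = generate(SynthConfig(n_u=12, n_v=12, n_edges=60, seed=4))
        train, probe = plant_probe(g, 0.1, seed=4)
        report = evaluate_fold(g, train, probe, method="pmil", seed=1)
        assert 0.0 <= report.auc <= 1.0
        assert 0.0 <= report.precision <= 1.0
        assert set(report.precision_at) == {10, 20, 50}
        assert all(0.0 <= v <= 1.0 for v in report.precision_at.values())

    def test_cross_validate_deterministic(self):
        g = generate(SynthConfig(n_u=10, n_v=10, n_edges=40, seed=6))
        a = cross_validate(g, method="cn", k=4, n_comparisons=500, seed=7)
        b = cross_validate(g, method="cn", k=4, n_comparisons=500, seed=7)
        assert [r.to_dict() for r in a] == [r.to_dict() for r in b]
        assert len(a) == 4

    def test_mean_report_is_arithmetic_mean(self):
        g = generate(SynthConfig(n_u=10, n_v=10, n_edges=40, seed=6))
        reports = cross_validate(g, method="jc", k=4, n_comparisons=500, seed=8)
        mean = mean_report(reports)
        assert mean.auc == pytest.approx(np.mean([r.auc for r in reports]))
        assert mean.precision == pytest.approx(
            np.mean([r.precision for r in reports])
        )
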