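"""Within-module path similarity, cross-module propagation and evaluation."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import random_weighted_graph
from pdcim.association_prediction import (
    build_bipartite_context,
    cross_module_score,
    evaluate_precision,
    path_similarity,
    rank_predictions,
    score_module_pair,
)
from pdcim.datasets import load_reported_ranking
from pdcim.io_formats import CuratedAssociationSet


def oracle_path_similarity(graph, a, b, aggregate="max", max_len=None):
    """Exhaustive simple-path enumeration, independent of the production DP."""
    if max_len is None:
        max_len = graph.number_of_nodes() - 1
    per_length = {}
    for path in nx.all_simple_paths(graph, a, b, cutoff=max_len):
        length = len(path) - 1
        weight = sum(graph[u][v]["weight"] for u, v in zip(path, path[1:]))
        per_length.setdefault(length, []).append(weight)
    total = 0.0
    for length, weights in per_length.items():
        if aggregate == "max":
            total += max(weights) / length
        else:
            total += (sum(weights) / len(weights)) / length
    return total


class TestPathSimilarity:
    def test_single_edge_recovers_weight(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.42)
        assert path_similarity(g, "a", "b") == pytest.approx(0.42)

    def test_triangle_hand_value(self, triangle):
        # direct edge 0.9 plus the two-edge path (0.6 + 0.8)/2
        assert path_similarity(triangle, "a", "c") == pytest.approx(1.6)

    def test_disconnected_pair_is_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_node("c")
        assert path_similarity(g, "a", "c") == 0.0

    def test_same_node_rejected(self, triangle):
        with pytest.raises(ValueError):
            path_similarity(triangle, "a", "a")

    def test_absent_node_rejected(self, triangle):
        with pytest.raises(ValueError, match="not in subgraph"):
            path_similarity(triangle, "a", "zz")

    def test_max_len_truncates(self, triangle):
        assert path_similarity(triangle, "a", "c", max_len=1) == pytest.approx(0.9)

    @pytest.mark.parametrize("aggregate", ["max", "mean"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed, aggregate):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        g = random_weighted_graph(rng, n, edge_prob=0.5)
        nodes = sorted(g.nodes)
        for a, b in itertools.combinations(nodes, 2):
            assert path_similarity(g, a, b, aggregate=aggregate) == pytest.approx(
                oracle_path_similarity(g, a, b, aggregate), abs=1e-12
            )


class TestBipartiteContext:
    def test_no_curated_links_empty_context(self, toy_pair):
        ctx = build_bipartite_context(
            toy_pair.drug_module,
            toy_pair.disease_module,
            toy_pair.drug_network,
            toy_pair.disease_network,
            CuratedAssociationSet({}),
        )
        assert ctx.known_links == frozenset()
        assert all(not ns for ns in ctx.disease_neighbors.values())
        assert all(not ns for ns in ctx.drug_neighbors.values())

    def test_worked_toy_has_five_known_links(self, toy_pair):
        ctx = build_bipartite_context(
            toy_pair.drug_module,
            toy_pair.disease_module,
            toy_pair.drug_network,
            toy_pair.disease_network,
            toy_pair.curated,
        )
        assert len(ctx.known_links) == 5

    def test_isolated_drug_has_empty_neighbor_set(self, toy_pair):
        drug_net = nx.Graph()
        drug_net.add_nodes_from(toy_pair.drug_module)  # no within-module edges
        ctx = build_bipartite_context(
            toy_pair.drug_module,
            toy_pair.disease_module,
            drug_net,
            toy_pair.disease_network,
            toy_pair.curated,
        )
        assert all(ns == frozenset() for ns in ctx.drug_neighbors.values())

    def test_empty_module_rejected(self, toy_pair):
        with pytest.raises(ValueError, match="empty module"):
            build_bipartite_context(
                frozenset(),
                toy_pair.disease_module,
                toy_pair.drug_network,
                toy_pair.disease_network,
                toy_pair.curated,
            )


def two_path_context(curated_records):
    """Minimal 2-drug / 2-disease context with edge weights 0.7 and 0.5."""
    drug_net = nx.Graph()
    drug_net.add_edge("w", "q", weight=0.5)
    dis_net = nx.Graph()
    dis_net.add_edge("v", "p", weight=0.7)
    return build_bipartite_context(
        {"w", "q"}, {"v", "p"}, drug_net, dis_net,
        CuratedAssociationSet(curated_records),
    )


class TestCrossModuleScore:
    def test_no_known_links_scores_zero(self, toy_pair):
        ctx = build_bipartite_context(
            toy_pair.drug_module,
            toy_pair.disease_module,
            toy_pair.drug_network,
            toy_pair.disease_network,
            CuratedAssociationSet({}),
        )
        for w in ctx.drugs:
            for v in ctx.diseases:
                assert cross_module_score(ctx, v, w) == 0.0

    def test_single_disease_side_term(self):
        # v's neighbor p (sim 0.7) is curated-linked to w; w's neighbor q
        # carries no link to v, so only the disease-side sum contributes.
        ctx = two_path_context({("w", "p"): "T"})
        assert cross_module_score(ctx, "v", "w") == pytest.approx(0.7)

    def test_both_sides_sum(self):
        # add the drug-side support: q curated-linked to v (sim(w,q)=0.5)
        ctx = two_path_context({("w", "p"): "T", ("q", "v"): "M"})
        assert cross_module_score(ctx, "v", "w") == pytest.approx(0.7 + 0.5)

    def test_one_sided_variants(self):
        ctx = two_path_context({("w", "p"): "T", ("q", "v"): "M"})
        assert cross_module_score(ctx, "v", "w", side="disease") == pytest.approx(0.7)
        assert cross_module_score(ctx, "v", "w", side="drug") == pytest.approx(0.5)

    def test_direct_bonus_term(self):
        ctx = two_path_context({("w", "v"): "M&T"})
        assert cross_module_score(ctx, "v", "w") == 0.0
        assert cross_module_score(ctx, "v", "w", direct_bonus=True) == 1.0

    def test_outside_nodes_rejected(self):
        ctx = two_path_context({("w", "p"): "T"})
        with pytest.raises(ValueError):
            cross_module_score(ctx, "nope", "w")
        with pytest.raises(ValueError):
            cross_module_score(ctx, "v", "nope")

    def test_adding_link_never_lowers_any_score(self, toy_pair):
        base_records = dict(toy_pair.curated.records)
        ctx = build_bipartite_context(
            toy_pair.drug_module, toy_pair.disease_module,
            toy_pair.drug_network, toy_pair.disease_network,
            toy_pair.curated,
        )
        before = {
            (w, v): cross_module_score(ctx, v, w)
            for w in ctx.drugs for v in ctx.diseases
        }
        extra = dict(base_records)
        extra[("drug2", "disease3")] = "T"
        ctx2 = build_bipartite_context(
            toy_pair.drug_module, toy_pair.disease_module,
            toy_pair.drug_network, toy_pair.disease_network,
            CuratedAssociationSet(extra),
        )
        for (w, v), s in before.items():
            assert cross_module_score(ctx2, v, w) >= s - 1e-12

    def test_removing_link_only_affects_adjacent_scores(self, toy_pair):
        """Dropping curated link (w0, p0) can only change scores of cells
        involving w0 (disease-side term) or a neighbor of p0 / p0's
        drug-side supporters — every cell with neither endpoint related
        stays put."""
        records = dict(toy_pair.curated.records)
        removed = ("drug4", "disease4")
        ctx_full = build_bipartite_context(
            toy_pair.drug_module, toy_pair.disease_module,
            toy_pair.drug_network, toy_pair.disease_network,
            CuratedAssociationSet(records),
        )
        del records[removed]
        ctx_less = build_bipartite_context(
            toy_pair.drug_module, toy_pair.disease_module,
            toy_pair.drug_network, toy_pair.disease_network,
            CuratedAssociationSet(records),
        )
        w0, p0 = removed
        for w in ctx_full.drugs:
            for v in ctx_full.diseases:
                a = cross_module_score(ctx_full, v, w)
                b = cross_module_score(ctx_less, v, w)
                if w != w0 and v != p0:
                    assert a == pytest.approx(b, abs=1e-12)


class TestRankPredictions:
    def test_all_cells_ranked_once(self, toy_pair):
        preds = score_module_pair(
            toy_pair.drug_module, toy_pair.disease_module,
            toy_pair.drug_network, toy_pair.disease_network, toy_pair.curated,
        )
        assert len(preds) == 16
        assert [p.rank for p in preds] == list(range(1, 17))
        assert all(
            preds[i].corr >= preds[i + 1].corr for i in range(len(preds) - 1)
        )

    def test_all_zero_scores_rank_lexicographically(self, toy_pair):
        preds = score_module_pair(
            toy_pair.drug_module, toy_pair.disease_module,
            toy_pair.drug_network, toy_pair.disease_network,
            CuratedAssociationSet({}),
        )
        cells = [(p.drug_id, p.disease_id) for p in preds]
        assert cells == sorted(cells)

    def test_dominant_pair_ranks_first(self):
        ctx = two_path_context({("w", "p"): "T"})
        scores = {
            (w, v): cross_module_score(ctx, v, w)
            for w in ctx.drugs for v in ctx.diseases
        }
        preds = rank_predictions(ctx, scores, CuratedAssociationSet({("w", "p"): "T"}))
        assert (preds[0].drug_id, preds[0].disease_id) == ("w", "v")

    def test_marks_attached_from_full_table(self, toy_pair):
        preds = score_module_pair(
            toy_pair.drug_module, toy_pair.disease_module,
            toy_pair.drug_network, toy_pair.disease_network, toy_pair.curated,
        )
        marked = {(p.drug_id, p.disease_id): p.curated_mark for p in preds}
        assert marked[("drug1", "disease1")] == "M&T"
        assert marked[("drug2", "disease4")] == "none"

    def test_incomplete_scores_rejected(self):
        ctx = two_path_context({("w", "p"): "T"})
        with pytest.raises(ValueError, match="cells"):
            rank_predictions(ctx, {("w", "v"): 1.0}, CuratedAssociationSet({}))


class TestEvaluatePrecision:
    @pytest.mark.parametrize(
        "which,expected",
        [(1, 0.90), (2, 0.80), (3, 0.90), ("baseline", 0.25)],
    )
    def test_reference_rankings(self, which, expected):
        df = load_reported_ranking(which)
        assert evaluate_precision(df.to_dict("records"), top_n=20) == pytest.approx(
            expected
        )

    def test_all_unknown_marks_zero(self):
        rows = [{"curated_mark": "none"}] * 5 + [{"curated_mark": "inferred"}] * 5
        assert evaluate_precision(rows, top_n=10) == 0.0

    def test_bad_top_n_rejected(self):
        rows = [{"curated_mark": "T"}] * 5
        with pytest.raises(ValueError):
            evaluate_precision(rows, top_n=0)
        with pytest.raises(ValueError):
            evaluate_precision(rows, top_n=6)
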