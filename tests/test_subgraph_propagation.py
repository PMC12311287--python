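"""Frontier expansion, attention, propagation and top-K selection."""

import numpy as np
import pytest

from biographfusion import autodiff as ad
from biographfusion.cp_semantics import init_factors
from biographfusion.kg_data import Triple, augment_graph, build_vocab
from biographfusion.params import init_params
from biographfusion.relation_refinement import init_refiner, refine_query_relation
from biographfusion.subgraph_propagation import (
    LayerParams,
    PropagationState,
    attention_weight,
    build_subgraph,
    expand_candidates,
    gumbel_topk_mask,
    importance_scores,
    propagate_layer,
    select_topk,
)


def random_kg(rng, n_entities=30, n_rel=3, n_facts=80):
    names = [f"n{i}" for i in range(n_entities)]
    raw = sorted(
        {
            (names[int(h)], f"r{int(r)}", names[int(t)])
            for h, r, t in rng.integers(0, [n_entities, n_rel, n_entities], size=(n_facts, 3))
        }
    )
    return augment_graph(raw, build_vocab(raw))


class TestExpandCandidates:
    def test_isolated_node_keeps_self_loop(self):
        kg = augment_graph([], build_vocab([("a", "r", "b")]))
        nodes, edges = expand_candidates(kg, {0})
        assert nodes == {0}
        assert edges == [Triple(0, kg.identity_relation, 0)]

    def test_chain_expansion(self):
        raw = [("a", "r", "b"), ("b", "r", "c")]
        kg = augment_graph(raw, build_vocab(raw))
        a, b = kg.vocab.entity_index["a"], kg.vocab.entity_index["b"]
        nodes, _ = expand_candidates(kg, {a})
        assert nodes == {a, b}

    def test_empty_frontier_raises(self, toy_kg):
        with pytest.raises(ValueError):
            expand_candidates(toy_kg, set())

    def test_matches_per_node_union(self, rng):
        kg = random_kg(rng)
        frontier = set(rng.choice(kg.n_entities, size=6, replace=False).tolist())
        nodes, edges = expand_candidates(kg, frontier)
        expected_nodes = set()
        expected_edges = []
        for v in sorted(frontier):
            for f in kg.facts.tolist():
                if f[0] == v:
                    expected_edges.append(Triple(*f))
                    expected_nodes.add(f[2])
        assert nodes == expected_nodes
        assert edges == sorted(expected_edges)
        assert frontier <= nodes  # identity loops guarantee carryover


class TestAttentionWeight:
    def _lp(self, rng, D=3):
        return LayerParams(
            W=rng.normal(size=(D, D)),
            W_alpha=rng.normal(size=(D, D)),
            w_alpha=rng.normal(size=D),
            W_samp=rng.normal(size=(1, D)),
        )

    def test_zero_attention_vector_gives_half(self, rng):
        lp = self._lp(rng)
        lp.w_alpha = np.zeros(3)
        a = attention_weight(lp, rng.normal(size=3), rng.normal(size=3), rng.normal(size=3))
        assert a == pytest.approx(0.5)

    def test_all_zero_inputs_give_half(self, rng):
        lp = self._lp(rng)
        z = np.zeros(3)
        assert attention_weight(lp, z, z, z) == pytest.approx(0.5)

    def test_matches_step_by_step_evaluation(self, rng):
        lp = self._lp(rng)
        h, e, q = (rng.normal(size=3) for _ in range(3))
        pre = lp.W_alpha @ (h + e + q)
        expected = 1.0 / (1.0 + np.exp(-lp.w_alpha @ np.maximum(pre, 0)))
        assert attention_weight(lp, h, e, q) == pytest.approx(expected, abs=1e-9)

    def test_always_in_unit_interval(self, rng):
        lp = self._lp(rng)
        for _ in range(50):
            a = attention_weight(
                lp, 5 * rng.normal(size=3), 5 * rng.normal(size=3), 5 * rng.normal(size=3)
            )
            assert 0.0 < a < 1.0


class TestPropagateLayer:
    def test_single_edge_hand_computed(self):
        factors = init_factors(3, 2, 2, seed=0, scale=0.0)
        refiner = init_refiner(2, seed=1)
        refiner.identity = True
        e_r = np.array([0.1, -0.2])
        h_a = np.array([0.3, 0.4])
        lp = LayerParams(
            W=np.eye(2), W_alpha=np.zeros((2, 2)), w_alpha=np.zeros(2),
            W_samp=np.zeros((1, 2)),
        )
        state = PropagationState(
            layer=0, frontier={0}, reps={0: h_a}, query_rel=np.zeros(2),
            edge_rels={(0, 0): e_r},
        )
        out = propagate_layer(state, [Triple(0, 0, 1)], lp, refiner, factors)
        # alpha = 0.5, W = I: h_1 = tanh(0.5 * (h_a + e_r))
        assert np.allclose(out[1], np.tanh(0.5 * (h_a + e_r)))

    def test_zero_transform_gives_zero_reps(self, rng):
        kg = random_kg(rng, n_entities=8, n_facts=15)
        factors = init_factors(8, kg.n_relations, 4, seed=0, scale=1.0)
        refiner = init_refiner(4, seed=1)
        lp = LayerParams(
            W=np.zeros((4, 4)), W_alpha=rng.normal(size=(4, 4)),
            w_alpha=rng.normal(size=4), W_samp=rng.normal(size=(1, 4)),
        )
        _, edges = expand_candidates(kg, {0})
        state = PropagationState(
            layer=0, frontier={0}, reps={0: factors.E_h[0]},
            query_rel=factors.E_r[0],
        )
        out = propagate_layer(state, edges, lp, refiner, factors)
        for v in out.values():
            assert np.allclose(v, 0.0)

    def test_matches_naive_dense_loop(self, rng):
        """8-node graph: vectorless reference built edge by edge."""
        kg = random_kg(rng, n_entities=8, n_rel=2, n_facts=20)
        D = 5
        factors = init_factors(8, kg.n_relations, D, seed=3, scale=1.0)
        refiner = init_refiner(D, seed=4)
        lp = LayerParams(
            W=rng.normal(size=(D, D)), W_alpha=rng.normal(size=(D, D)),
            w_alpha=rng.normal(size=D), W_samp=rng.normal(size=(1, D)),
        )
        frontier = {0, 1, 2}
        reps = {v: factors.E_h[v] for v in frontier}
        q_rel = rng.normal(size=D)
        _, edges = expand_candidates(kg, frontier)
        state = PropagationState(
            layer=0, frontier=frontier, reps=reps, query_rel=q_rel
        )
        out = propagate_layer(state, edges, lp, refiner, factors)
        # naive: per-node loop over all edges, explicit refinement
        from biographfusion.relation_refinement import lstm_step

        tails = {e.tail for e in edges}
        for t in tails:
            acc = np.zeros(D)
            for e in edges:
                if e.tail != t:
                    continue
                e_r, _ = lstm_step(refiner, factors.E_r[e.relation], factors.E_h[e.head])
                alpha = attention_weight(lp, reps[e.head], e_r, q_rel)
                acc += alpha * (reps[e.head] + e_r)
            assert np.allclose(out[t], np.tanh(lp.W @ acc), atol=1e-7)

    def test_edge_with_head_outside_frontier_rejected(self, toy_kg, rng):
        factors = init_factors(toy_kg.n_entities, toy_kg.n_relations, 3, seed=0)
        refiner = init_refiner(3, seed=1)
        lp = LayerParams(
            W=np.eye(3), W_alpha=np.zeros((3, 3)), w_alpha=np.zeros(3),
            W_samp=np.zeros((1, 3)),
        )
        state = PropagationState(
            layer=0, frontier={0}, reps={0: factors.E_h[0]},
            query_rel=factors.E_r[0],
        )
        with pytest.raises(ValueError):
            propagate_layer(state, [Triple(1, 0, 2)], lp, refiner, factors)


class TestImportanceScores:
    def test_zero_row_gives_zero_scores(self, rng):
        reps = {i: rng.normal(size=4) for i in range(5)}
        assert set(importance_scores(np.zeros((1, 4)), reps).values()) == {0.0}

    def test_unit_row_selects_component(self, rng):
        reps = {i: rng.normal(size=4) for i in range(5)}
        w = np.zeros((1, 4))
        w[0, 2] = 1.0
        scores = importance_scores(w, reps)
        for i, r in reps.items():
            assert scores[i] == pytest.approx(r[2])

    def test_dot_product_oracle(self, rng):
        w = rng.normal(size=(1, 6))
        reps = {i: rng.normal(size=6) for i in range(8)}
        scores = importance_scores(w, reps)
        for i, r in reps.items():
            assert scores[i] == pytest.approx(float(w[0] @ r))


class TestSelectTopK:
    def test_exact_topk_with_sorting(self):
        assert select_topk({0: 0.9, 1: 0.1, 2: 0.5}, 2) == {0, 2}

    def test_k_larger_than_candidates_keeps_all(self):
        scores = {0: 0.3, 1: 0.1}
        assert select_topk(scores, 10, "infer") == {0, 1}
        assert select_topk(scores, 10, "train", seed=1) == {0, 1}

    def test_ties_broken_by_ascending_index(self):
        assert select_topk({3: 1.0, 1: 1.0, 2: 1.0}, 2) == {1, 2}

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            select_topk({0: 1.0}, 0)

    def test_infer_matches_sort_oracle_randomized(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 9))
            scores = {i: float(x) for i, x in enumerate(rng.normal(size=n))}
            K = int(rng.integers(1, 9))
            got = select_topk(scores, K, "infer")
            oracle = sorted(scores, key=lambda i: (-scores[i], i))[:K]
            assert got == set(oracle)

    def test_low_temperature_concentrates_on_exact_topk(self, rng):
        scores = {i: float(x) for i, x in enumerate(rng.normal(size=10))}
        exact = select_topk(scores, 3, "infer")
        agree = sum(
            select_topk(scores, 3, "train", temperature=0.01, seed=s) == exact
            for s in range(200)
        )
        assert agree >= 190  # >= 95 %


class TestGumbelTopKMask:
    def test_infer_mask_matches_reference_per_segment(self, rng):
        segments = np.sort(rng.integers(0, 3, size=25))
        s = rng.normal(size=25)
        mask, selected = gumbel_topk_mask(s, segments, 3, 4, "infer", 1.0, None)
        for q in range(3):
            rows = np.nonzero(segments == q)[0]
            scores = {int(i): float(s[i]) for i in rows}
            expected = select_topk(scores, 4, "infer")
            assert set(rows[selected[rows]].tolist()) == expected

    def test_train_hard_selection_sizes(self, rng):
        segments = np.sort(rng.integers(0, 4, size=40))
        s = ad.Tensor(rng.normal(size=40))
        _, selected = gumbel_topk_mask(
            s, segments, 4, 5, "train", 1.0, np.random.default_rng(0)
        )
        for q in range(4):
            rows = segments == q
            assert selected[rows].sum() == min(5, rows.sum())

    def test_straight_through_gradient_nonzero_on_selected(self, rng):
        segments = np.zeros(8, dtype=np.int64)
        s = ad.Tensor(rng.normal(size=8))
        mask, selected = gumbel_topk_mask(
            s, segments, 1, 3, "train", 1.0, np.random.default_rng(5)
        )
        loss = (mask * rng.normal(size=8)).sum()
        loss.backward()
        assert s.grad is not None
        assert np.any(np.abs(s.grad[selected]) > 1e-12)

    def test_backward_matches_explicit_pick_jacobians(self, rng):
        segments = np.sort(rng.integers(0, 3, size=20))
        s = ad.Tensor(rng.normal(size=20))
        draw = np.random.default_rng(7)
        tau = 0.6
        mask, _ = gumbel_topk_mask(s, segments, 3, 2, "train", tau, draw)
        g = rng.normal(size=20)
        mask.backward(g)
        # reconstruct per-pick softmax Jacobians with the same Gumbel draw
        draw2 = np.random.default_rng(7)
        pert = s.data + tau * draw2.gumbel(size=20)
        grad = np.zeros(20)
        for q in range(3):
            rows = np.nonzero(segments == q)[0]
            live = np.ones(len(rows), bool)
            for _ in range(min(2, len(rows))):
                z = np.where(live, pert[rows] / tau, -np.inf)
                p = np.exp(z - z.max())
                p[~live] = 0
                p /= p.sum()
                gq = g[rows]
                grad[rows] += (p * gq - p * (p @ gq)) / tau
                live[np.argmax(z)] = False
        assert np.allclose(s.grad, grad, atol=1e-10)

    def test_force_row_replaces_weakest_pick(self, rng):
        segments = np.zeros(6, dtype=np.int64)
        s = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        mask, selected = gumbel_topk_mask(
            s, segments, 1, 2, "infer", 1.0, None, force_rows=np.array([5])
        )
        assert selected[5] and selected[0] and not selected[1]
        assert selected.sum() == 2


class TestBuildSubgraph:
    def _params(self, kg, D=4, n_layers=2, seed=0, K=50):
        return init_params(
            kg.n_entities, kg.n_relations, D, n_layers, seed=seed,
            init_scale=0.5, top_k=K, trainable=False,
        )

    def test_zero_layers_gives_query_singleton(self, toy_kg):
        params = self._params(toy_kg, n_layers=0)
        sub, q_rel = build_subgraph(toy_kg, (0, 0), params, 0, 5)
        assert sub.nodes == {0}
        assert sub.edges == set()
        assert np.allclose(sub.final_reps[0], params.factors.E_h[0])

    def test_chain_reachability_two_layers(self):
        raw = [("a", "r", "b"), ("b", "r", "c"), ("c", "r", "d")]
        kg = augment_graph(raw, build_vocab(raw))
        vi = kg.vocab.entity_index
        params = self._params(kg)
        sub, _ = build_subgraph(kg, (vi["a"], 0), params, 2, 100)
        assert vi["c"] in sub.nodes  # exactly 2 hops away
        assert vi["d"] not in sub.nodes  # 3 hops away

    def test_frontier_never_exceeds_k(self, rule_kg):
        params = self._params(rule_kg, n_layers=3, K=5)
        sub, _ = build_subgraph(rule_kg, (0, 0), params, 3, 5)
        assert len(sub.nodes) <= 5

    def test_reachability_soundness(self, rule_kg, rng):
        """Every selected node lies within n_layers hops of the query."""
        n_layers = 3
        params = self._params(rule_kg, n_layers=n_layers, K=8)
        qe = int(rng.integers(rule_kg.n_entities))
        sub, _ = build_subgraph(rule_kg, (qe, 0), params, n_layers, 8)
        reach = {qe}
        for _ in range(n_layers):
            _, edges = expand_candidates(rule_kg, reach)
            reach |= {e.tail for e in edges}
        assert sub.nodes <= reach

    def test_matches_manual_layerwise_simulation(self, rng):
        kg = random_kg(rng, n_entities=12, n_rel=2, n_facts=25)
        D, L, K = 4, 2, 4
        params = self._params(kg, D=D, n_layers=L, K=K)
        qe, qr = 1, 0
        sub, q_rel = build_subgraph(kg, (qe, qr), params, L, K)
        # manual simulation of expand -> refine -> propagate -> score -> select
        factors = params.factors
        refiner = params.refiner
        e_qe = factors.E_h[qe].copy()
        state = PropagationState(
            layer=0, frontier={qe}, reps={qe: e_qe},
            query_rel=factors.E_r[qr].copy(),
        )
        for layer in range(L):
            lp = params.layer_np(layer)
            state.query_rel = refine_query_relation(refiner, state.query_rel, e_qe)
            _, edges = expand_candidates(kg, state.frontier)
            reps_new = propagate_layer(state, edges, lp, refiner, factors)
            from biographfusion.relation_refinement import refine_edge_relations

            prev = {
                (e.head, e.relation): state.edge_rels.get(
                    (e.head, e.relation), factors.E_r[e.relation]
                )
                for e in edges
            }
            state.edge_rels.update(
                refine_edge_relations(refiner, edges, prev, factors)
            )
            scores = importance_scores(params.W_samp, reps_new)
            chosen = select_topk(scores, K, "infer")
            if qe in reps_new and qe not in chosen:
                worst = max(chosen, key=lambda t: (-scores[t], t))
                chosen.discard(worst)
                chosen.add(qe)
            state.frontier = chosen
            state.reps = {t: reps_new[t] for t in chosen}
        assert sub.nodes == state.frontier
        assert np.allclose(q_rel, state.query_rel)
        for t in sub.nodes:
            assert np.allclose(sub.final_reps[t], state.reps[t])


class TestExportSubgraph:
    def test_tsv_rows_cover_traversed_edges_with_unit_interval_alphas(
        self, rule_kg, tmp_path
    ):
        from biographfusion.subgraph_propagation import export_subgraph

        params = init_params(
            rule_kg.n_entities, rule_kg.n_relations, 4, 2, seed=3,
            init_scale=0.5, top_k=6, trainable=False,
        )
        path = tmp_path / "subgraph.tsv"
        n = export_subgraph(rule_kg, (0, 0), params, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "head\trelation\ttail\tlayer\talpha"
        assert len(lines) == n + 1
        layers = set()
        for line in lines[1:]:
            head, rel, tail, layer, alpha = line.split("\t")
            assert 0.0 < float(alpha) < 1.0
            layers.add(int(layer))
        assert layers <= {1, 2}
        assert 1 in layers
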