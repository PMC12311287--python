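"""Query-guided subgraph construction and propagation.

Starting from the query entity, each layer (i) expands the frontier to all
outgoing neighbours, (ii) refines edge and query relation embeddings with
the contextual refiner, (iii) aggregates query-attentive messages into
candidate representations, (iv) scores each candidate's relevance with a
linear readout and (v) keeps the top ``K`` candidates.  At inference the
selection is exact top-K (ties broken by ascending entity index); during
training it is a sequence of Gumbel-perturbed hard argmax picks without
replacement whose backward pass uses the softmax relaxation's gradient
(straight-through).

The functions in this module are the per-query reference implementations;
the batched training engine in :mod:`biographfusion.model` computes the
same quantities vectorized over queries and is tested against them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .cp_semantics import CPFactors
from .kg_data import KnowledgeGraph, Triple
from .relation_refinement import (
    RelationRefiner,
    refine_edge_relations,
    refine_query_relation,
)

logger = logging.getLogger(__name__)

MASK_NEG = -1e30  # additive mask standing in for -inf in perturbed logits


@dataclass
class LayerParams:
    """Per-layer message/attention weights plus the shared scoring row.

    ``W`` transforms aggregated messages, ``W_alpha``/``w_alpha`` parameterize
    the per-edge attention gate, and ``W_samp`` (shared across layers) maps a
    representation to its scalar relevance score.
    """

    W: object  # (D, D)
    W_alpha: object  # (D, D)
    w_alpha: object  # (D,)
    W_samp: object  # (1, D), shared across layers


@dataclass
class PropagationState:
    """Per-query state after layer ``layer`` of propagation."""

    layer: int
    frontier: set
    reps: dict  # entity -> (D,) vector, keyed exactly by frontier
    query_rel: object  # (D,) refined query-relation embedding
    edge_rels: dict = field(default_factory=dict)  # (head, rel) -> (D,)


@dataclass
class Subgraph:
    """Final query-specific subgraph with node representations."""

    nodes: set
    edges: set  # of Triple
    final_reps: dict


def expand_candidates(kg: KnowledgeGraph, frontier):
    """Candidate nodes and edges reachable one hop from ``frontier``.

    Candidate edges are every augmented fact whose head is in the frontier;
    candidate nodes are their tails.  Identity self-loops guarantee the
    frontier itself stays reachable.
    """
    if not frontier:
        raise ValueError("cannot expand an empty frontier")
    edges = [Triple(*row) for row in kg.outgoing(frontier).tolist()]
    nodes = {e.tail for e in edges}
    return nodes, edges


def attention_weight(layer_params: LayerParams, h_head, e_rel, e_qrel):
    """Per-edge attention gate in (0, 1).

    ``alpha = sigmoid(w_alpha^T ReLU(W_alpha (h_head + e_rel + e_qrel)))``:
    the gate sees the head's current representation, the refined edge
    relation and the refined query relation, so propagation is steered by
    the query context.
    """
    z = ad.data(h_head) + ad.data(e_rel) + ad.data(e_qrel)
    hidden = np.maximum(ad.data(layer_params.W_alpha) @ z, 0.0)
    logit = float(ad.data(layer_params.w_alpha) @ hidden)
    return float(1.0 / (1.0 + np.exp(-logit)))


def propagate_layer(
    state: PropagationState,
    candidate_edges,
    layer_params: LayerParams,
    refiner: RelationRefiner,
    factors: CPFactors,
) -> dict:
    """Aggregate attentive messages into each candidate's representation.

    ``h_t = tanh(W . sum_{(h,r,t)} alpha_{h,r,t} (h_h + e_r))`` where the
    edge relation embeddings come from :func:`refine_edge_relations` (with
    the previous layer's values as input) and the attention uses the
    state's refined query relation.
    """
    E_r = ad.data(factors.E_r)
    for e in candidate_edges:
        if e.head not in state.frontier:
            raise ValueError(f"edge {tuple(e)} has head outside the frontier")
    prev = {
        (e.head, e.relation): state.edge_rels.get(
            (e.head, e.relation), E_r[e.relation]
        )
        for e in candidate_edges
    }
    refined = refine_edge_relations(refiner, candidate_edges, prev, factors)
    sums: dict = {}
    for e in candidate_edges:
        h_h = ad.data(state.reps[e.head])
        e_r = ad.data(refined[(e.head, e.relation)])
        alpha = attention_weight(layer_params, h_h, e_r, state.query_rel)
        msg = alpha * (h_h + e_r)
        if e.tail in sums:
            sums[e.tail] = sums[e.tail] + msg
        else:
            sums[e.tail] = msg
    W = ad.data(layer_params.W)
    return {t: np.tanh(W @ s) for t, s in sums.items()}


def importance_scores(W_samp, reps: dict) -> dict:
    """Scalar relevance score ``s_t = W_samp . h_t`` per candidate."""
    if not reps:
        raise ValueError("no candidate representations to score")
    row = ad.data(W_samp).reshape(-1)
    return {t: float(row @ ad.data(h)) for t, h in reps.items()}


def select_topk(
    scores: dict,
    K: int,
    mode: str = "infer",
    temperature: float = 1.0,
    seed: int = 0,
) -> set:
    """Keep ``min(K, n)`` candidates by relevance score.

    Inference: exact top-K, ties broken by ascending entity index.
    Training: K successive hard argmax picks (without replacement) of the
    scores perturbed by ``temperature``-scaled Gumbel(0, 1) noise.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if mode not in ("infer", "train"):
        raise ValueError(f"unknown selection mode {mode!r}")
    ids = np.array(sorted(scores), dtype=np.int64)
    vals = np.array([scores[i] for i in ids], dtype=np.float64)
    if mode == "train":
        rng = np.random.default_rng(seed)
        vals = vals + temperature * rng.gumbel(size=vals.shape)
    order = np.lexsort((ids, -vals))
    return set(ids[order[: min(K, len(ids))]].tolist())


def gumbel_topk_mask(
    scores,
    segments: np.ndarray,
    n_segments: int,
    K: int,
    mode: str,
    temperature: float,
    rng,
    force_rows=None,
):
    """Straight-through top-K over contiguous score segments.

    ``scores`` is a length-C vector (Tensor while training) of candidate
    scores grouped by ``segments`` (sorted, one segment per query).  Returns
    ``(mask, selected)``: ``selected`` is the boolean hard selection and
    ``mask`` equals 1 on selected rows in the forward pass while carrying
    the softmax relaxation's gradient in the backward pass.

    ``force_rows`` optionally gives rows that must always be retained,
    shape ``(n_segments,)`` or ``(n_segments, F)`` with -1 padding: the
    query node always, plus (during training) the answer entity, which the
    AdaProp-style sampling lineage keeps in the subgraph so the training
    signal always reaches it.  A forced row that was not picked replaces
    the weakest pick, so the selection size never exceeds
    ``min(K, segment size)``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    s_data = ad.data(scores)
    C = s_data.shape[0]
    starts = np.searchsorted(segments, np.arange(n_segments))
    stops = np.searchsorted(segments, np.arange(n_segments), side="right")
    sizes = stops - starts

    if mode == "infer":
        order = np.lexsort((np.arange(C), -s_data, segments))
        rank = np.arange(C) - np.repeat(starts, sizes)
        selected = np.zeros(C, dtype=bool)
        selected[order[rank < K]] = True
        _apply_force(selected, order, starts, np.minimum(K, sizes), force_rows)
        return selected.astype(np.float64), selected

    if mode != "train":
        raise ValueError(f"unknown selection mode {mode!r}")

    tau = max(temperature, 1e-12)
    gumbel = rng.gumbel(size=C)
    pert_data = s_data + temperature * gumbel
    n_picks = np.minimum(K, sizes)
    # Because the Gumbel perturbation is fixed for the whole selection round,
    # K successive argmax picks without replacement are exactly the top
    # n_picks rows of the perturbed scores (ties by ascending index).
    order = np.lexsort((np.arange(C), -pert_data, segments))
    rank = np.arange(C) - np.repeat(starts, sizes)
    picked_sorted = rank < np.repeat(n_picks, sizes)
    selected = np.zeros(C, dtype=bool)
    selected[order[picked_sorted]] = True
    _apply_force(selected, order, starts, n_picks, force_rows)
    hard = selected.astype(np.float64)
    if not ad.is_tensor(scores):
        return hard, selected

    # Straight-through backward: the gradient of the summed per-pick softmax
    # relaxations p_k (softmax over the candidates still unselected at pick
    # k), i.e. sum_k (diag(p_k) - p_k p_k^T) / tau per segment.  In the
    # sorted order, pick k's live set is exactly ranks >= k, so every term
    # reduces to segment-wise suffix/prefix sums.
    seg_sorted = segments  # contiguous; `order` keeps segment blocks in place
    stops_m1 = stops - 1
    z = pert_data[order] / tau
    e = np.exp(z - np.repeat(z[starts], sizes))  # per-segment max is rank 0

    def backward(g):
        gs = g[order]
        S = _suffix_sum(e, seg_sorted, stops_m1)  # S_k = sum_{j>=k} e_j
        T = _suffix_sum(e * gs, seg_sorted, stops_m1)
        u = np.where(picked_sorted, 1.0 / S, 0.0)
        v = np.where(picked_sorted, T / (S * S), 0.0)
        A = _prefix_sum(u, starts)
        Bv = _prefix_sum(v, starts)
        grad_sorted = e / tau * (gs * A - Bv)
        grad = np.empty(C)
        grad[order] = grad_sorted
        return [(scores, grad)]

    mask = ad.Tensor(hard, parents=(scores,), backward=backward)
    return mask, selected


def _suffix_sum(x, segments, stops_m1):
    """Within-segment suffix sums: out[j] = sum_{i >= j, same segment} x[i]."""
    cs = np.cumsum(x)
    return cs[stops_m1][segments] - cs + x


def _prefix_sum(x, starts):
    """Within-segment prefix (inclusive) sums."""
    cs = np.cumsum(x)
    offset = np.concatenate(([0.0], cs))[starts]
    sizes = np.diff(np.concatenate((starts, [len(x)])))
    return cs - np.repeat(offset, sizes)


def _apply_force(selected, order, starts, n_picks, force_rows):
    """Force-retain rows per segment, swapping out the weakest picks.

    ``order`` is the per-segment priority order (best first); weakest picks
    are dropped from the tail, never dropping another forced row.
    """
    if force_rows is None:
        return
    force_rows = np.asarray(force_rows)
    if force_rows.ndim == 1:
        force_rows = force_rows[:, None]
    for q in range(force_rows.shape[0]):
        forced = {int(r) for r in force_rows[q] if r >= 0}
        if not forced:
            continue
        drop_rank = int(n_picks[q]) - 1
        for row in sorted(forced):
            if selected[row]:
                continue
            while drop_rank >= 0 and int(order[starts[q] + drop_rank]) in forced:
                drop_rank -= 1
            if drop_rank < 0:
                break
            drop = int(order[starts[q] + drop_rank])
            if not selected[drop]:
                break
            selected[drop] = False
            selected[row] = True
            drop_rank -= 1
            logger.debug("force-retained row %d (dropped %d)", row, drop)


def export_subgraph(
    kg: KnowledgeGraph,
    query,
    params,
    path,
    n_layers: int | None = None,
    K: int | None = None,
) -> int:
    """Write a query's traversed edges with attention weights as TSV.

    Columns: head, relation, tail, layer, alpha (entity/relation names).
    Supports pathway-style inspection of what the propagation attended
    to.  Returns the number of rows written.
    """
    qe, qr = (query.qe, query.qr) if hasattr(query, "qe") else tuple(query)
    n_layers = params.n_layers if n_layers is None else n_layers
    K = params.top_k if K is None else K
    factors = params.factors.detached()
    refiner = params.refiner.detached()
    query_refiner = params.query_refiner_detached()
    e_qe, e_qr = params.query_embeddings_np(qe, qr)
    state = PropagationState(layer=0, frontier={qe}, reps={qe: e_qe}, query_rel=e_qr)
    rows = []
    for layer in range(n_layers):
        lp = params.layer_np(layer)
        state.query_rel = refine_query_relation(query_refiner, state.query_rel, e_qe)
        _, cand_edges = expand_candidates(kg, state.frontier)
        if not cand_edges:
            break
        prev = {
            (e.head, e.relation): state.edge_rels.get(
                (e.head, e.relation), ad.data(factors.E_r)[e.relation]
            )
            for e in cand_edges
        }
        from .relation_refinement import refine_edge_relations

        refined = refine_edge_relations(refiner, cand_edges, prev, factors)
        for e in cand_edges:
            alpha = attention_weight(
                lp, state.reps[e.head], refined[(e.head, e.relation)], state.query_rel
            )
            rows.append((e, layer + 1, alpha))
        reps_new = propagate_layer(state, cand_edges, lp, refiner, factors)
        state.edge_rels.update(refined)
        scores = importance_scores(params.W_samp_np(), reps_new)
        chosen = select_topk(scores, K, "infer")
        if qe in reps_new and qe not in chosen:
            worst = max(chosen, key=lambda t: (-scores[t], t))
            chosen.discard(worst)
            chosen.add(qe)
        state = replace(
            state, layer=layer + 1, frontier=chosen,
            reps={t: reps_new[t] for t in chosen},
        )
    vocab = kg.vocab
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("head\trelation\ttail\tlayer\talpha\n")
        for e, layer, alpha in rows:
            fh.write(
                f"{vocab.entity_names[e.head]}\t"
                f"{vocab.augmented_relation_name(e.relation)}\t"
                f"{vocab.entity_names[e.tail]}\t{layer}\t{alpha:.6f}\n"
            )
    return len(rows)


def build_subgraph(
    kg: KnowledgeGraph,
    query,
    params,
    n_layers: int,
    K: int,
    mode: str = "infer",
    seed: int = 0,
):
    """Iterate expand / refine / propagate / select for ``n_layers``.

    ``query`` is ``(qe, qr)`` (or an object with those attributes);
    ``params`` is a :class:`biographfusion.params.ModelParams`.  Returns the
    final :class:`Subgraph` and the refined query-relation embedding.
    Deterministic in infer mode.
    """
    qe, qr = (query.qe, query.qr) if hasattr(query, "qe") else tuple(query)
    factors = params.factors.detached()
    refiner = params.refiner.detached()
    query_refiner = params.query_refiner_detached()
    e_qe, e_qr = params.query_embeddings_np(qe, qr)
    state = PropagationState(
        layer=0, frontier={qe}, reps={qe: e_qe}, query_rel=e_qr
    )
    edges_by_layer = []
    for layer in range(n_layers):
        lp = params.layer_np(layer)
        state.query_rel = refine_query_relation(query_refiner, state.query_rel, e_qe)
        try:
            _, cand_edges = expand_candidates(kg, state.frontier)
        except ValueError:
            cand_edges = []
        if not cand_edges:
            logger.warning(
                "propagation stopped at layer %d: empty candidate set", layer + 1
            )
            break
        reps_new = propagate_layer(state, cand_edges, lp, refiner, factors)
        # cache refined pair embeddings for the next layer's refinement input
        prev = {
            (e.head, e.relation): state.edge_rels.get(
                (e.head, e.relation), ad.data(factors.E_r)[e.relation]
            )
            for e in cand_edges
        }
        state.edge_rels.update(
            refine_edge_relations(refiner, cand_edges, prev, factors)
        )
        scores = importance_scores(params.W_samp_np(), reps_new)
        chosen = select_topk(scores, K, mode, params.temperature, seed + layer)
        if qe in reps_new and qe not in chosen:
            worst = max(chosen, key=lambda t: (-scores[t], t))
            chosen.discard(worst)
            chosen.add(qe)
            logger.debug("force-retained query node %d (dropped %d)", qe, worst)
        edges_by_layer.append([e for e in cand_edges])
        state = replace(
            state,
            layer=layer + 1,
            frontier=chosen,
            reps={t: reps_new[t] for t in chosen},
        )
    nodes = set(state.frontier)
    if params.subgraph_edges == "final" and edges_by_layer:
        pool = edges_by_layer[-1]
    else:
        pool = [e for layer_edges in edges_by_layer for e in layer_edges]
    edges = {e for e in pool if e.head in nodes and e.tail in nodes}
    return Subgraph(nodes=nodes, edges=edges, final_reps=dict(state.reps)), (
        state.query_rel
    )
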