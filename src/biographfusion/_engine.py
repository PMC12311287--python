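"""Vectorized multi-query forward pass and composite loss.

This is the computational core shared by training and evaluation: the same
layer-by-layer construction as the per-query reference functions in
:mod:`biographfusion.subgraph_propagation`, but batched over queries by
keeping the frontier as parallel ``(query, entity)`` arrays and the edge
set as flat index arrays.  With Tensor-valued parameters the pass records
an autodiff tape; with plain arrays it is tape-free numpy.
"""

from __future__ import annotations

import logging

import numpy as np

from . import autodiff as ad
from .kg_data import KnowledgeGraph
from .params import ModelParams
from .relation_refinement import lstm_step
from .subgraph_propagation import gumbel_topk_mask

logger = logging.getLogger(__name__)


def forward_scores(
    kg: KnowledgeGraph,
    params: ModelParams,
    qe: np.ndarray,
    qr: np.ndarray,
    mode: str = "infer",
    rng=None,
    exclude_answers: np.ndarray | None = None,
    answer_guidance: float = 0.0,
    top_k: int | None = None,
):
    """Hybrid scores ``(B, |V|)`` and refined query relations ``(B, D)``.

    ``exclude_answers`` (training only) gives the answer entity of each
    query; the fact ``(qe, qr, qa)`` and its inverse are then hidden from
    that query's expansion, so the structural branch cannot shortcut
    through the very edge it is being trained to predict.

    ``answer_guidance`` is the scheduled-sampling probability with which a
    training query's answer is force-retained in the selected frontier.
    Early in training the answer would rarely survive top-K selection, so
    no learning signal reaches it and the structural branch can collapse
    into scoring every reached entity low; guiding the selection toward
    the answer (and annealing the probability to zero so the selection
    must eventually retain it on merit) makes the takeoff reliable.
    """
    qe = np.asarray(qe, dtype=np.int64)
    qr = np.asarray(qr, dtype=np.int64)
    B, nV = len(qe), kg.n_entities
    nR = kg.n_relations
    flags = params.ablation
    E_h, E_r, E_t = params.factors.E_h, params.factors.E_r, params.factors.E_t

    if flags.random_query:
        eqe = params.rand_ent[qe]
        eqr = params.rand_rel[qr]
    else:
        eqe = ad.gather(E_h, qe)
        eqr = ad.gather(E_r, qr)

    if flags.no_gsp:
        phi = (eqe * eqr) @ _t(E_t)
        return phi, eqr

    refiner = params.refiner
    qrefiner = params.query_refiner or params.refiner
    crr = not refiner.identity

    qa = exclude_answers
    guided = np.zeros(B, dtype=bool)
    if qa is not None and answer_guidance > 0.0 and mode == "train":
        guided = rng.random(B) < answer_guidance
    if qa is not None:
        n_base = kg.n_base_relations
        qr_inv = np.where(
            qr < n_base, qr + n_base, np.where(qr < 2 * n_base, qr - n_base, qr)
        )

    f_query = np.arange(B, dtype=np.int64)
    f_node = qe.copy()
    h = eqe
    rel_bank = E_r  # rows 0..nR-1 are the base embeddings
    bank_rows = nR
    rel_cache: dict = {}

    for layer in range(params.n_layers):
        if crr:
            eqr, _ = lstm_step(qrefiner, eqr, eqe)
        # ---- frontier expansion (pure index bookkeeping) ----
        indptr = kg._indptr
        starts, stops = indptr[f_node], indptr[f_node + 1]
        counts = stops - starts
        total = int(counts.sum())
        if total == 0:
            logger.warning(
                "propagation stopped at layer %d: no outgoing edges", layer + 1
            )
            break
        e_src = np.repeat(np.arange(len(f_node)), counts)
        idx = np.repeat(stops - np.cumsum(counts), counts) + np.arange(total)
        e_rel = kg.facts[idx, 1]
        e_tail = kg.facts[idx, 2]
        e_head = f_node[e_src]
        e_q = f_query[e_src]
        if qa is not None:
            fwd = (
                (e_head == qe[e_q]) & (e_rel == qr[e_q]) & (e_tail == qa[e_q])
            )
            bwd = (
                (e_head == qa[e_q]) & (e_rel == qr_inv[e_q]) & (e_tail == qe[e_q])
            )
            keep = ~(fwd | bwd)
            if not keep.all():
                e_src, e_rel = e_src[keep], e_rel[keep]
                e_tail, e_head, e_q = e_tail[keep], e_head[keep], e_q[keep]
                if e_q.size == 0:
                    logger.warning(
                        "all candidate edges masked at layer %d", layer + 1
                    )
                    break
        # ---- candidate nodes: unique (query, tail) ----
        cand_key, e_cand = np.unique(e_q * nV + e_tail, return_inverse=True)
        cand_q = cand_key // nV
        cand_node = cand_key % nV
        C = len(cand_key)
        # ---- contextual relation refinement with cross-layer cache ----
        if not crr:
            edge_rel = ad.gather(E_r, e_rel)
        else:
            pair_key, p_inv = np.unique(
                (e_q * nV + e_head) * nR + e_rel, return_inverse=True
            )
            p_r = pair_key % nR
            p_h = (pair_key // nR) % nV
            sel = np.array(
                [rel_cache.get(int(k), int(r)) for k, r in zip(pair_key, p_r)],
                dtype=np.int64,
            )
            prev = ad.gather(rel_bank, sel)
            hidden = ad.gather(E_h, p_h)
            refined, _ = lstm_step(refiner, prev, hidden)
            for i, k in enumerate(pair_key):
                rel_cache[int(k)] = bank_rows + i
            rel_bank = ad.concat([rel_bank, refined], axis=0)
            bank_rows += len(pair_key)
            edge_rel = ad.gather(refined, p_inv)
        # ---- query-attentive message passing ----
        lp = params.layers[layer]
        h_head = ad.gather(h, e_src)
        base = h_head + edge_rel
        hidden_a = ad.relu((base + ad.gather(eqr, e_q)) @ _t(lp.W_alpha))
        alpha = ad.sigmoid(hidden_a @ _col(lp.w_alpha))
        msg = alpha * base
        agg = ad.segment_sum(msg, e_cand, C)
        h_new = ad.tanh(agg @ _t(lp.W))
        # ---- relevance scoring and top-K filtering ----
        s = (h_new @ _t(params.W_samp)).reshape(-1)
        force_rows = np.full((B, 2), -1, dtype=np.int64)
        qe_rows = np.nonzero(cand_node == qe[cand_q])[0]
        force_rows[cand_q[qe_rows], 0] = qe_rows
        if guided.any():
            qa_rows = np.nonzero(
                (cand_node == qa[cand_q]) & guided[cand_q]
            )[0]
            force_rows[cand_q[qa_rows], 1] = qa_rows
        mask, selected = gumbel_topk_mask(
            s, cand_q, B, top_k or params.top_k, mode, params.temperature,
            rng, force_rows,
        )
        sel_rows = np.nonzero(selected)[0]
        f_query = cand_q[sel_rows]
        f_node = cand_node[sel_rows]
        mask_sel = ad.gather(mask, sel_rows)
        h = ad.gather(h_new, sel_rows) * mask_sel.reshape((-1, 1))

    # ---- hybrid scoring ----
    f_vals = (h @ _t(params.readout)).reshape(-1)
    f_mat = ad.scatter_pairs(f_vals, f_query, f_node, (B, nV))
    if flags.no_phi:
        return f_mat, eqr
    phi = (eqe * eqr) @ _t(E_t)
    lam = params.fusion_weight
    return lam * f_mat + (1.0 - lam) * phi, eqr


def batch_loss(
    kg: KnowledgeGraph,
    params: ModelParams,
    queries: np.ndarray,
    gamma: float,
    reg_kind: str = "n3",
    mode: str = "train",
    rng=None,
    answer_guidance: float = 0.0,
    top_k: int | None = None,
):
    """Mean multi-class log-loss over the batch plus the mean regularizer.

    The log-loss softmax spans every entity (other true answers included;
    filtering is an evaluation-time concept only).  The penalty is applied
    to the query-entity embedding, the refined query relation at the final
    layer and the answer embedding, averaged over the batch.
    """
    queries = np.asarray(queries, dtype=np.int64).reshape(-1, 3)
    B = len(queries)
    if B == 0:
        raise ValueError("batch must be non-empty")
    qe, qr, qa = queries[:, 0], queries[:, 1], queries[:, 2]
    scores, eqr_final = forward_scores(
        kg, params, qe, qr, mode=mode, rng=rng, exclude_answers=qa,
        answer_guidance=answer_guidance, top_k=top_k,
    )
    if not np.all(np.isfinite(ad.data(scores))):
        raise FloatingPointError("non-finite scores encountered in forward pass")
    lse = ad.logsumexp(scores, axis=1)
    ans = ad.take_pairs(scores, np.arange(B), qa)
    loss = (lse - ans).mean() if ad.is_tensor(scores) else float(np.mean(lse - ans))
    if gamma > 0.0:
        if params.ablation.random_query:
            e_qe = params.rand_ent[qe]
        else:
            e_qe = ad.gather(params.factors.E_h, qe)
        e_qa = ad.gather(params.factors.E_t, qa)
        p = {"n3": 3, "l2": 2, "l1": 1}[reg_kind]
        penalty = 0.0
        for v in (e_qe, eqr_final, e_qa):
            penalty = penalty + (ad.absolute(v) ** p).sum() * (1.0 / B)
        loss = loss + gamma * penalty
    return loss


def _t(m):
    return m.T if isinstance(m, ad.Tensor) else np.asarray(m).T


def _col(v):
    return v.reshape((-1, 1)) if isinstance(v, ad.Tensor) else np.asarray(v).reshape(-1, 1)
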