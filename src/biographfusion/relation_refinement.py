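"""Contextual relation refinement (CRR).

Relations in biomedical graphs are context dependent: "disease_gene" can
stand for different mechanisms depending on the entities it connects.  The
refiner is a single-step LSTM cell applied once per propagation layer: the
relation embedding is the cell input, the (static) head-entity embedding is
the recurrent hidden state, and the cell state is reset to zero at every
call, so the refinement is a deterministic function of (relation embedding,
entity embedding).  The same cell re-embeds each edge relation conditioned
on its head entity, and the query relation conditioned on the query entity.

With the ablation flag set (``identity=True``) the refine operations are
exact pass-throughs, which is the "no CRR" model variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .cp_semantics import CPFactors

_GATES = ("i", "f", "o", "c")


@dataclass
class RelationRefiner:
    """Gate weight blocks: input weight W, recurrent weight U, bias b per gate."""

    weights: dict  # {"Wi","Ui","bi","Wf","Uf","bf","Wo","Uo","bo","Wc","Uc","bc"}
    identity: bool = False

    @property
    def D(self) -> int:
        return ad.data(self.weights["Wi"]).shape[0]

    def detached(self) -> "RelationRefiner":
        return RelationRefiner(
            {k: ad.data(v) for k, v in self.weights.items()}, self.identity
        )


def init_refiner(D: int, seed: int, scale: float | None = None) -> RelationRefiner:
    """Near-pass-through initialization of the refiner cell.

    Gate weights are Normal(0, scale) with ``scale`` defaulting to
    1/sqrt(D).  The input and output gate biases start at +1 and the
    candidate weight at the identity (plus noise), so at initialization the
    refined embedding approximately preserves the incoming relation
    embedding instead of collapsing it toward zero (gates at 0.5 and a
    random candidate cell would shrink every relation to a small, nearly
    relation-independent vector, erasing the signal the attention needs).
    Context sensitivity is then learned on top of the pass-through.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(D) if scale is None else scale
    w = {}
    for g in _GATES:
        w[f"W{g}"] = rng.normal(0.0, scale, size=(D, D))
        w[f"U{g}"] = rng.normal(0.0, scale, size=(D, D))
        w[f"b{g}"] = np.zeros(D)
    w["Wc"] = np.eye(D) + rng.normal(0.0, scale / 4.0, size=(D, D))
    w["bi"] = np.ones(D)
    w["bo"] = np.ones(D)
    return RelationRefiner(w)


def lstm_step(refiner: RelationRefiner, x, hidden, cell=0.0):
    """One gated-cell update; ``x`` and ``hidden`` are (..., D) rows.

    i = sigmoid(Wi x + Ui h + bi), f = sigmoid(Wf x + Uf h + bf),
    o = sigmoid(Wo x + Uo h + bo), c~ = tanh(Wc x + Uc h + bc),
    c' = f * cell + i * c~,  output = o * tanh(c').
    """
    w = refiner.weights
    if ad.data(x).shape[-1] != refiner.D or ad.data(hidden).shape[-1] != refiner.D:
        raise ValueError("input/hidden dimension mismatch with refiner")
    if ad.data(x).ndim == 2:
        return _lstm_step_batched(refiner, x, hidden, cell)
    # gates spelled out (transposed weights applied on the right so that the
    # same code handles both single vectors and row-stacked batches)
    gi = ad.sigmoid(_affine(x, hidden, w, "i"))
    gf = ad.sigmoid(_affine(x, hidden, w, "f"))
    go = ad.sigmoid(_affine(x, hidden, w, "o"))
    gc = ad.tanh(_affine(x, hidden, w, "c"))
    new_cell = gf * cell + gi * gc
    return go * ad.tanh(new_cell), new_cell


def _lstm_step_batched(refiner: RelationRefiner, x, hidden, cell=0.0):
    """Row-batched cell update with the four gate products fused."""
    w = refiner.weights
    D = refiner.D
    WT = ad.concat([_t(w[f"W{g}"]) for g in _GATES], axis=1)  # (D, 4D)
    UT = ad.concat([_t(w[f"U{g}"]) for g in _GATES], axis=1)
    b = ad.concat([w[f"b{g}"].reshape((1, D)) for g in _GATES], axis=1)
    z = x @ WT + hidden @ UT + b
    gates = ad.sigmoid(ad.slice_cols(z, 0, 3 * D))
    gi = ad.slice_cols(gates, 0, D)
    gf = ad.slice_cols(gates, D, 2 * D)
    go = ad.slice_cols(gates, 2 * D, 3 * D)
    gc = ad.tanh(ad.slice_cols(z, 3 * D, 4 * D))
    if isinstance(cell, float) and cell == 0.0:
        new_cell = gi * gc
    else:
        new_cell = gf * cell + gi * gc
    return go * ad.tanh(new_cell), new_cell


def _affine(x, hidden, w, gate):
    W, U, b = w[f"W{gate}"], w[f"U{gate}"], w[f"b{gate}"]
    return x @ _t(W) + hidden @ _t(U) + b


def _t(m):
    return m.T if isinstance(m, ad.Tensor) else np.asarray(m).T


def refine_edge_relations(
    refiner: RelationRefiner, edges, prev_rel_embeddings: dict, factors: CPFactors
) -> dict:
    """Refine each edge's relation embedding conditioned on its head entity.

    ``prev_rel_embeddings`` maps ``(head, relation)`` to the embedding from
    the previous layer (base ``E_r`` rows at layer 0).  Edges sharing a
    (head, relation) pair get identical refined embeddings; the LSTM hidden
    state is the static CP head-entity row.
    """
    if refiner.identity:
        return dict(prev_rel_embeddings)
    E_h = ad.data(factors.E_h)
    pairs = sorted({(e[0], e[1]) for e in edges})
    out = {}
    for h, r in pairs:
        if (h, r) not in prev_rel_embeddings:
            raise KeyError(f"no previous relation embedding for pair {(h, r)}")
        refined, _ = lstm_step(refiner, prev_rel_embeddings[(h, r)], E_h[h])
        out[(h, r)] = refined
    return out


def refine_query_relation(refiner: RelationRefiner, e_qr_prev, e_qe):
    """Refine the query relation conditioned on the query entity."""
    if refiner.identity:
        return e_qr_prev
    out, _ = lstm_step(refiner, e_qr_prev, e_qe)
    return out
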