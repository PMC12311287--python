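"""Hybrid structural + semantic triple scoring.

The final score of a candidate answer is a convex combination
``f~ = lambda * f + (1 - lambda) * phi`` of a structural readout
``f = w^T h_qa`` (dot product of a learned vector with the candidate's final
propagated representation; 0 if the candidate was never reached) and the CP
semantic score ``phi`` computed with the refined query relation, so the
semantic branch can still rank entities the structural walk missed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .cp_semantics import cp_score_all
from .kg_data import KnowledgeGraph
from .params import AblationFlags, ModelParams
from .subgraph_propagation import build_subgraph


@dataclass
class ScoreConfig:
    """Fusion weight, readout vector and ablation switches."""

    fusion_weight: float = 0.7  # lambda in [0, 1]
    readout: object = None  # (D,) or (1, D) vector w
    ablation: AblationFlags = field(default_factory=AblationFlags)

    def __post_init__(self):
        if not 0.0 <= self.fusion_weight <= 1.0:
            raise ValueError("fusion weight must lie in [0, 1]")


def structural_score(readout, rep) -> float:
    """``w^T h`` for a reached candidate; 0 for an unreached one.

    The zero convention (rather than -inf) keeps the training softmax
    finite and lets the semantic branch rank unreached entities.
    """
    if rep is None:
        return 0.0
    return float(ad.data(readout).reshape(-1) @ ad.data(rep).reshape(-1))


def hybrid_score(config: ScoreConfig, f: float, phi: float) -> float:
    """``lambda * f + (1 - lambda) * phi`` with the ablation overrides.

    ``no_phi`` forces the fusion weight to 1 (structural only); ``no_gsp``
    returns the raw semantic score (scale-free for ranking, but documented:
    phi is *not* rescaled by 1 - lambda in that variant).
    """
    if config.ablation.no_gsp:
        return float(phi)
    if config.ablation.no_phi:
        return float(f)
    lam = config.fusion_weight
    return float(lam * f + (1.0 - lam) * phi)


def score_all_entities(
    model: ModelParams,
    kg: KnowledgeGraph,
    query,
    mode: str = "infer",
    seed: int = 0,
) -> np.ndarray:
    """Hybrid scores of every entity for a ``(qe, qr, ?)`` query.

    Reference composition of the module operations: build the query
    subgraph (unless ``no_gsp``), read out structural scores from its final
    representations, compute the semantic score vector with the refined
    query relation, and fuse.  Deterministic in infer mode.
    """
    qe, qr = (query.qe, query.qr) if hasattr(query, "qe") else tuple(query)
    nV = kg.n_entities
    if not (0 <= qe < nV and 0 <= qr < kg.n_relations):
        raise KeyError(f"query ({qe}, {qr}) outside vocabulary")
    config = ScoreConfig(
        fusion_weight=model.fusion_weight,
        readout=model.readout,
        ablation=model.ablation,
    )
    factors = model.factors.detached()
    if model.ablation.no_gsp:
        _, e_qr0 = model.query_embeddings_np(qe, qr)
        phi = _phi_vector(model, factors, qe, e_qr0)
        return phi
    subgraph, e_qr_final = build_subgraph(
        kg, (qe, qr), model, model.n_layers, model.top_k, mode, seed
    )
    f = np.zeros(nV)
    for t, rep in subgraph.final_reps.items():
        f[t] = structural_score(model.readout, rep)
    phi = _phi_vector(model, factors, qe, e_qr_final)
    lam = model.fusion_weight
    if model.ablation.no_phi:
        return f
    return lam * f + (1.0 - lam) * phi


def _phi_vector(model: ModelParams, factors, qe: int, e_qr) -> np.ndarray:
    """Semantic score against every tail, honouring the BGF-R ablation."""
    if model.ablation.random_query:
        e_qe = model.rand_ent[qe]
        return ad.data(factors.E_t) @ (e_qe * ad.data(e_qr))
    return cp_score_all(factors, qe, e_qr)


def ranked_predictions(
    model: ModelParams, kg: KnowledgeGraph, query, top: int = 10
) -> list:
    """Per-query ranked list of (entity name, hybrid score) tuples."""
    scores = score_all_entities(model, kg, query)
    order = np.lexsort((np.arange(len(scores)), -scores))[:top]
    return [(kg.vocab.entity_names[i], float(scores[i])) for i in order]


def prediction_table(
    model: ModelParams, kg: KnowledgeGraph, query, top: int = 10
) -> list:
    """Ranked rows ``(entity name, hybrid score, f, phi, rank)``.

    The structural (f) and semantic (phi) components are reported
    separately so predictions can be traced to the branch that drove them.
    """
    qe, qr = (query.qe, query.qr) if hasattr(query, "qe") else tuple(query)
    factors = model.factors.detached()
    nV = kg.n_entities
    f = np.zeros(nV)
    if model.ablation.no_gsp:
        _, e_qr = model.query_embeddings_np(qe, qr)
    else:
        subgraph, e_qr = build_subgraph(
            kg, (qe, qr), model, model.n_layers, model.top_k, "infer", 0
        )
        for t, rep in subgraph.final_reps.items():
            f[t] = structural_score(model.readout, rep)
    phi = _phi_vector(model, factors, qe, e_qr)
    config = ScoreConfig(
        fusion_weight=model.fusion_weight,
        readout=model.readout,
        ablation=model.ablation,
    )
    hybrid = np.array([hybrid_score(config, f[t], phi[t]) for t in range(nV)])
    order = np.lexsort((np.arange(nV), -hybrid))[:top]
    return [
        (
            kg.vocab.entity_names[t],
            float(hybrid[t]),
            float(f[t]),
            float(phi[t]),
            rank + 1,
        )
        for rank, t in enumerate(order)
    ]
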