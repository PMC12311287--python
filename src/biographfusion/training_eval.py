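"""Composite loss, filtered ranking evaluation and the ablation variants.

Evaluation follows the filtered ranking protocol: for a query
``(qe, qr, ?)`` the true answer is ranked against all entities after the
scores of *other* known true answers (from train, valid and test, in either
direction) are removed; ties are resolved pessimistically, i.e. the answer
is ranked below every competitor with an equal score.  Reported metrics are
the mean reciprocal rank (MRR) and Hit@k for k = 1 and 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp as _np_logsumexp

from . import _engine
from . import autodiff as ad
from .kg_data import KnowledgeGraph
from .params import AblationFlags, ModelParams

ABLATION_VARIANTS = ("bgf_wo_gsp", "bgf_r", "bgf_wo_crr", "bgf_wo_phi")


@dataclass
class TrainConfig:
    """Model and optimizer settings.

    Defaults follow the reference configuration: batch size 16, embedding
    dimension 32, fusion weight 0.7 and 6 propagation steps; N3
    regularization with strength ``gamma``.
    """

    embedding_dim: int = 32
    n_layers: int = 6
    top_k: int = 100
    fusion_weight: float = 0.7
    gamma: float = 1e-3
    reg_kind: str = "n3"
    lr: float = 1e-3
    optimizer: str = "adam"
    weight_decay: float = 0.0
    lr_decay: float = 0.5
    lr_patience: int = 5
    clip_norm: float | None = 1.0
    epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    temperature: float = 1.0
    init_scale: float = 0.1
    patience: int = 10
    eval_every: int = 1
    train_inverse: bool = True
    warmstart_epochs: int = 0
    answer_guidance_epochs: int = 0
    k_anneal_epochs: int = 0
    separate_query_refiner: bool = False
    subgraph_edges: str = "all"
    ablation: AblationFlags = field(default_factory=AblationFlags)

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.reg_kind not in ("n3", "l1", "l2"):
            raise ValueError("reg_kind must be one of n3, l1, l2")
        if not 0.0 <= self.fusion_weight <= 1.0:
            raise ValueError("fusion_weight must lie in [0, 1]")


@dataclass
class RankingResult:
    """Filtered per-query ranks with their aggregate metrics."""

    per_query_ranks: list
    mrr: float
    hit1: float
    hit10: float

    @classmethod
    def from_ranks(cls, ranks) -> "RankingResult":
        ranks = [int(r) for r in ranks]
        arr = np.asarray(ranks, dtype=np.float64)
        if arr.size == 0:
            return cls([], 0.0, 0.0, 0.0)
        return cls(
            per_query_ranks=ranks,
            mrr=float(np.mean(1.0 / arr)),
            hit1=float(np.mean(arr <= 1)),
            hit10=float(np.mean(arr <= 10)),
        )

    def summary(self) -> dict:
        return {
            "mrr": self.mrr,
            "hit1": self.hit1,
            "hit10": self.hit10,
            "n_queries": len(self.per_query_ranks),
        }


def log_loss(scores: np.ndarray, answer: int) -> float:
    """Multi-class log-loss ``-s[answer] + log sum_t exp(s[t])``."""
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("log_loss requires finite scores")
    return float(_np_logsumexp(scores) - scores[answer])


def total_loss(
    batch_queries,
    model: ModelParams,
    config: TrainConfig,
    kg: KnowledgeGraph,
    mode: str = "train",
    rng=None,
):
    """Mean log-loss plus ``gamma`` times the mean embedding penalty.

    Returns a float for tape-free parameters and an autodiff Tensor for
    trainable ones (call ``.backward()`` for gradients).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _engine.batch_loss(
        kg,
        model,
        batch_queries,
        gamma=config.gamma,
        reg_kind=config.reg_kind,
        mode=mode,
        rng=rng,
    )


def filtered_rank(scores: np.ndarray, answer: int, known_answers) -> int:
    """Pessimistic filtered rank of ``answer`` within ``scores``.

    Other known answers are removed from the ranking; equal-scoring
    competitors all rank ahead of the answer.
    """
    if answer not in known_answers:
        raise ValueError("answer must be among the known answers")
    s = np.array(scores, dtype=np.float64)
    others = [t for t in known_answers if t != answer]
    if others:
        s[np.asarray(others, dtype=np.int64)] = -np.inf
    return int(np.sum(s >= s[answer]))


def evaluate(
    model: ModelParams,
    kg: KnowledgeGraph,
    split: str = "test",
    batch_size: int = 128,
    include_inverse: bool = False,
) -> RankingResult:
    """Filtered MRR / Hit@1 / Hit@10 over a query split (infer mode)."""
    queries = kg.split_queries(split, include_inverse=include_inverse)
    if len(queries) == 0:
        raise ValueError(f"split {split!r} is empty")
    known = kg.known_answers()
    params = model.detached()
    ranks = []
    for lo in range(0, len(queries), batch_size):
        chunk = queries[lo : lo + batch_size]
        scores, _ = _engine.forward_scores(
            kg, params, chunk[:, 0], chunk[:, 1], mode="infer"
        )
        scores = ad.data(scores)
        for row, (h, r, t) in zip(scores, chunk.tolist()):
            ranks.append(filtered_rank(row, t, known.get((h, r), {t})))
    return RankingResult.from_ranks(ranks)


def apply_ablation(config: TrainConfig, variant: str) -> TrainConfig:
    """The four model variants as configuration transforms.

    ``bgf_wo_gsp``: semantic branch only (no propagation); ``bgf_r``:
    fixed random query embeddings; ``bgf_wo_crr``: identity relation
    refinement; ``bgf_wo_phi``: structural branch only (fusion weight 1,
    loss keeps its regularizer).
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(
            f"unknown ablation variant {variant!r}; expected one of "
            f"{ABLATION_VARIANTS}"
        )
    flags = AblationFlags(
        no_gsp=variant == "bgf_wo_gsp",
        random_query=variant == "bgf_r",
        no_crr=variant == "bgf_wo_crr",
        no_phi=variant == "bgf_wo_phi",
    )
    out = replace(config, ablation=flags)
    if variant == "bgf_wo_phi":
        out = replace(out, fusion_weight=1.0)
    return out


def train(kg: KnowledgeGraph, config: TrainConfig):
    """Fit the full model under ``config``; returns (params, history).

    Thin wrapper over the :class:`biographfusion.model.BioGraphFusion`
    estimator, which owns the optimization loop.
    """
    from .model import BioGraphFusion

    est = BioGraphFusion.from_config(config)
    est.fit(kg)
    return est.params_, est.history_
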