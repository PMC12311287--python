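"""The BioGraphFusion estimator.

A scikit-learn style model for knowledge-graph completion: ``fit`` takes a
:class:`~biographfusion.kg_data.KnowledgeGraph` (with train/valid/test
query splits) and jointly optimizes the CP factor matrices, the contextual
relation refiner and the propagation/attention/readout weights under the
composite loss (multi-class log-loss over all entities + the embedding
penalty).  ``predict`` answers ``(head, relation, ?)`` queries with the
hybrid structural+semantic score.

Training uses Adam over the package's autodiff tape, mini-batches of
queries (each training fact also contributes its inverse query by
default), and early stopping on validation MRR.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator

from . import _engine
from . import autodiff as ad
from .kg_data import KnowledgeGraph
from .params import AblationFlags, init_params
from .training_eval import (
    ABLATION_VARIANTS,
    RankingResult,
    TrainConfig,
    apply_ablation,
    evaluate,
)

logger = logging.getLogger(__name__)


class BioGraphFusion(BaseEstimator):
    """Hybrid CP-semantic / query-guided-propagation link predictor.

    Parameters mirror :class:`~biographfusion.training_eval.TrainConfig`;
    ``ablation`` may be ``None``, an :class:`AblationFlags` instance or one
    of the variant names ``bgf_wo_gsp``, ``bgf_r``, ``bgf_wo_crr``,
    ``bgf_wo_phi``.

    Attributes set by :meth:`fit` (trailing underscore): ``params_`` (all
    trained arrays), ``history_`` (per-epoch loss / validation MRR),
    ``n_entities_``, ``n_relations_``, ``best_valid_mrr_``.
    """

    def __init__(
        self,
        embedding_dim: int = 32,
        n_layers: int = 6,
        top_k: int = 100,
        fusion_weight: float = 0.7,
        gamma: float = 1e-3,
        reg_kind: str = "n3",
        lr: float = 1e-3,
        optimizer: str = "adam",
        weight_decay: float = 0.0,
        lr_decay: float = 0.5,
        lr_patience: int = 5,
        clip_norm: float | None = 1.0,
        epochs: int = 100,
        batch_size: int = 16,
        temperature: float = 1.0,
        init_scale: float = 0.1,
        patience: int = 10,
        eval_every: int = 1,
        train_inverse: bool = True,
        warmstart_epochs: int = 0,
        answer_guidance_epochs: int = 0,
        k_anneal_epochs: int = 0,
        separate_query_refiner: bool = False,
        subgraph_edges: str = "all",
        ablation=None,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.n_layers = n_layers
        self.top_k = top_k
        self.fusion_weight = fusion_weight
        self.gamma = gamma
        self.reg_kind = reg_kind
        self.lr = lr
        self.optimizer = optimizer
        self.weight_decay = weight_decay
        self.lr_decay = lr_decay
        self.lr_patience = lr_patience
        self.clip_norm = clip_norm
        self.epochs = epochs
        self.batch_size = batch_size
        self.temperature = temperature
        self.init_scale = init_scale
        self.patience = patience
        self.eval_every = eval_every
        self.train_inverse = train_inverse
        self.warmstart_epochs = warmstart_epochs
        self.answer_guidance_epochs = answer_guidance_epochs
        self.k_anneal_epochs = k_anneal_epochs
        self.separate_query_refiner = separate_query_refiner
        self.subgraph_edges = subgraph_edges
        self.ablation = ablation
        self.random_state = random_state
        self.verbose = verbose

    # -- configuration glue ----------------------------------------------
    @classmethod
    def from_config(cls, config: TrainConfig) -> "BioGraphFusion":
        return cls(
            embedding_dim=config.embedding_dim,
            n_layers=config.n_layers,
            top_k=config.top_k,
            fusion_weight=config.fusion_weight,
            gamma=config.gamma,
            reg_kind=config.reg_kind,
            lr=config.lr,
            optimizer=config.optimizer,
            weight_decay=config.weight_decay,
            lr_decay=config.lr_decay,
            lr_patience=config.lr_patience,
            clip_norm=config.clip_norm,
            epochs=config.epochs,
            batch_size=config.batch_size,
            temperature=config.temperature,
            init_scale=config.init_scale,
            patience=config.patience,
            eval_every=config.eval_every,
            train_inverse=config.train_inverse,
            warmstart_epochs=config.warmstart_epochs,
            answer_guidance_epochs=config.answer_guidance_epochs,
            k_anneal_epochs=config.k_anneal_epochs,
            separate_query_refiner=config.separate_query_refiner,
            subgraph_edges=config.subgraph_edges,
            ablation=config.ablation,
            random_state=config.seed,
        )

    def _config(self) -> TrainConfig:
        return TrainConfig(
            embedding_dim=self.embedding_dim,
            n_layers=self.n_layers,
            top_k=self.top_k,
            fusion_weight=self.fusion_weight,
            gamma=self.gamma,
            reg_kind=self.reg_kind,
            lr=self.lr,
            optimizer=self.optimizer,
            weight_decay=self.weight_decay,
            lr_decay=self.lr_decay,
            lr_patience=self.lr_patience,
            clip_norm=self.clip_norm,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
            temperature=self.temperature,
            init_scale=self.init_scale,
            patience=self.patience,
            eval_every=self.eval_every,
            train_inverse=self.train_inverse,
            warmstart_epochs=self.warmstart_epochs,
            answer_guidance_epochs=self.answer_guidance_epochs,
            k_anneal_epochs=self.k_anneal_epochs,
            separate_query_refiner=self.separate_query_refiner,
            subgraph_edges=self.subgraph_edges,
            ablation=self._flags(),
        )

    def _flags(self) -> AblationFlags:
        if self.ablation is None:
            return AblationFlags()
        if isinstance(self.ablation, AblationFlags):
            return self.ablation
        if self.ablation in ABLATION_VARIANTS:
            return apply_ablation(TrainConfig(), self.ablation).ablation
        raise ValueError(f"unrecognized ablation {self.ablation!r}")

    # -- fitting -----------------------------------------------------------
    def fit(self, X: KnowledgeGraph, y=None) -> "BioGraphFusion":
        if not isinstance(X, KnowledgeGraph):
            raise TypeError("X must be a KnowledgeGraph")
        cfg = self._config()
        if cfg.ablation.no_phi:
            cfg = replace(cfg, fusion_weight=1.0)
        kg = X
        train_q = kg.split_queries("train", include_inverse=cfg.train_inverse)
        if len(train_q) == 0:
            raise ValueError("train split is empty")
        params = init_params(
            kg.n_entities,
            kg.n_relations,
            cfg.embedding_dim,
            cfg.n_layers,
            seed=cfg.seed,
            init_scale=cfg.init_scale,
            fusion_weight=cfg.fusion_weight,
            temperature=cfg.temperature,
            top_k=cfg.top_k,
            subgraph_edges=cfg.subgraph_edges,
            ablation=cfg.ablation,
            separate_query_refiner=cfg.separate_query_refiner,
            avg_degree=len(kg.facts) / max(1, kg.n_entities),
        )
        opt_cls = {"adam": ad.Adam, "adagrad": ad.Adagrad}[cfg.optimizer]
        opt = opt_cls(
            params.tensors(), lr=cfg.lr,
            weight_decay=cfg.weight_decay, clip_norm=cfg.clip_norm,
        )
        rng = np.random.default_rng([cfg.seed, 91])
        has_valid = len(kg.query_splits.get("valid", ())) > 0
        history: list = []
        best_mrr, best_snap, bad = -np.inf, None, 0
        base_flags = params.ablation
        for epoch in range(1, cfg.epochs + 1):
            if cfg.warmstart_epochs and epoch <= cfg.warmstart_epochs:
                # CP warm-start: semantic branch only for the first epochs
                params.ablation = replace(base_flags, no_gsp=True)
            else:
                params.ablation = base_flags
            perm = rng.permutation(len(train_q))
            epoch_loss = 0.0
            for lo in range(0, len(perm), cfg.batch_size):
                batch = train_q[perm[lo : lo + cfg.batch_size]]
                opt.zero_grad()
                # scheduled sampling: guide selection toward the answer
                # early on, annealing linearly to zero
                guidance = max(
                    0.0, 1.0 - (epoch - 1) / cfg.answer_guidance_epochs
                ) if cfg.answer_guidance_epochs > 0 else 0.0
                # K continuation: start with full coverage, anneal to top_k
                k_train = None
                if cfg.k_anneal_epochs > 0 and epoch <= cfg.k_anneal_epochs:
                    frac = (epoch - 1) / cfg.k_anneal_epochs
                    k_train = int(round(
                        kg.n_entities + frac * (cfg.top_k - kg.n_entities)
                    ))
                    k_train = max(k_train, cfg.top_k)
                try:
                    loss = _engine.batch_loss(
                        kg,
                        params,
                        batch,
                        gamma=cfg.gamma,
                        reg_kind=cfg.reg_kind,
                        mode="train",
                        rng=rng,
                        answer_guidance=guidance,
                        top_k=k_train,
                    )
                except FloatingPointError as exc:
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: {exc}"
                    ) from exc
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(batch)
            epoch_loss /= len(train_q)
            record = {"epoch": epoch, "loss": epoch_loss}
            if has_valid and epoch % cfg.eval_every == 0:
                val = evaluate(params, kg, "valid")
                record["valid_mrr"] = val.mrr
                if val.mrr > best_mrr + 1e-12:
                    best_mrr, best_snap, bad = val.mrr, params.snapshot(), 0
                else:
                    bad += 1
                    # halve the step size when validation stalls
                    if cfg.lr_decay < 1.0 and bad > 0 and bad % cfg.lr_patience == 0:
                        opt.lr *= cfg.lr_decay
                        record["lr"] = opt.lr
            history.append(record)
            if self.verbose:
                logger.info("epoch %d: %s", epoch, record)
            if has_valid and bad >= cfg.patience:
                break
        params.ablation = base_flags
        if best_snap is not None:
            params.restore(best_snap)
        self.params_ = params
        self.history_ = history
        self.n_entities_ = kg.n_entities
        self.n_relations_ = kg.n_relations
        self.best_valid_mrr_ = best_mrr if has_valid else None
        self.kg_ = kg
        return self

    # -- prediction --------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted; call fit first")

    def decision_function(self, X) -> np.ndarray:
        """Hybrid scores ``(n_queries, n_entities)`` for (qe, qr) pairs."""
        self._check_fitted()
        pairs = np.asarray(X, dtype=np.int64).reshape(-1, 2)
        scores, _ = _engine.forward_scores(
            self.kg_, self.params_.detached(), pairs[:, 0], pairs[:, 1], mode="infer"
        )
        return ad.data(scores)

    def predict(self, X) -> np.ndarray:
        """Highest-scoring tail entity index for each (qe, qr) pair."""
        return np.argmax(self.decision_function(X), axis=1)

    def score_entities(self, qe: int, qr: int) -> np.ndarray:
        """Score every entity as the answer of one query."""
        return self.decision_function([(qe, qr)])[0]

    def evaluate(self, split: str = "test") -> RankingResult:
        """Filtered ranking metrics of the fitted model on a query split."""
        self._check_fitted()
        return evaluate(self.params_, self.kg_, split)
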