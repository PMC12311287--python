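"""All trainable parameters of the model, plus the ablation switches.

``ModelParams`` bundles the CP factor matrices, the contextual relation
refiner, the per-layer propagation/attention weights, the shared relevance
scoring row and the readout vector.  During training every array is a
:class:`~biographfusion.autodiff.Tensor`; :meth:`ModelParams.detached`
yields a tape-free view for inference and evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .cp_semantics import CPFactors, init_factors
from .relation_refinement import RelationRefiner, init_refiner
from .subgraph_propagation import LayerParams


@dataclass(frozen=True)
class AblationFlags:
    """Behavioural switches for the four model variants.

    ``no_gsp``: drop structural propagation entirely (pure CP scoring with
    the base query relation); ``random_query``: replace the query entity
    and relation embeddings with fixed random vectors; ``no_crr``: relation
    refinement is an identity pass-through; ``no_phi``: drop the semantic
    branch from the hybrid score (fusion weight forced to 1).
    """

    no_gsp: bool = False
    random_query: bool = False
    no_crr: bool = False
    no_phi: bool = False


@dataclass
class ModelParams:
    """Trainable state plus the non-trainable run settings it implies."""

    factors: CPFactors
    refiner: RelationRefiner
    layers: list  # of LayerParams (W_samp shared across layers)
    W_samp: object  # (1, D)
    readout: object  # (1, D)
    query_refiner: RelationRefiner | None = None  # None: shared with `refiner`
    rand_ent: np.ndarray = None  # fixed random query-entity rows (ablation)
    rand_rel: np.ndarray = None
    fusion_weight: float = 0.7
    temperature: float = 1.0
    top_k: int = 100
    subgraph_edges: str = "all"
    ablation: AblationFlags = field(default_factory=AblationFlags)

    # -- derived views ---------------------------------------------------
    @property
    def D(self) -> int:
        return self.factors.D

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def query_refiner_detached(self) -> RelationRefiner:
        ref = self.query_refiner if self.query_refiner is not None else self.refiner
        return ref.detached()

    def layer_np(self, layer: int) -> LayerParams:
        lp = self.layers[layer]
        return LayerParams(
            W=ad.data(lp.W),
            W_alpha=ad.data(lp.W_alpha),
            w_alpha=ad.data(lp.w_alpha),
            W_samp=ad.data(self.W_samp),
        )

    def W_samp_np(self) -> np.ndarray:
        return ad.data(self.W_samp)

    def query_embeddings_np(self, qe: int, qr: int):
        """Query entity / initial relation embeddings (honours BGF-R)."""
        if self.ablation.random_query:
            return self.rand_ent[qe].copy(), self.rand_rel[qr].copy()
        return ad.data(self.factors.E_h)[qe].copy(), ad.data(self.factors.E_r)[
            qr
        ].copy()

    # -- training plumbing ----------------------------------------------
    def tensors(self) -> dict:
        """Flat ``{name: Tensor}`` view of every trainable array."""
        out = {
            "E_h": self.factors.E_h,
            "E_r": self.factors.E_r,
            "E_t": self.factors.E_t,
            "W_samp": self.W_samp,
            "readout": self.readout,
        }
        for k, v in self.refiner.weights.items():
            out[f"lstm.{k}"] = v
        if self.query_refiner is not None:
            for k, v in self.query_refiner.weights.items():
                out[f"qlstm.{k}"] = v
        for i, lp in enumerate(self.layers):
            out[f"layer{i}.W"] = lp.W
            out[f"layer{i}.W_alpha"] = lp.W_alpha
            out[f"layer{i}.w_alpha"] = lp.w_alpha
        return {k: v for k, v in out.items() if isinstance(v, ad.Tensor)}

    def detached(self) -> "ModelParams":
        """Tape-free view sharing the underlying arrays."""
        ref = RelationRefiner(
            {k: ad.data(v) for k, v in self.refiner.weights.items()},
            self.refiner.identity,
        )
        qref = None
        if self.query_refiner is not None:
            qref = RelationRefiner(
                {k: ad.data(v) for k, v in self.query_refiner.weights.items()},
                self.query_refiner.identity,
            )
        W_samp = ad.data(self.W_samp)
        layers = [
            LayerParams(
                W=ad.data(lp.W),
                W_alpha=ad.data(lp.W_alpha),
                w_alpha=ad.data(lp.w_alpha),
                W_samp=W_samp,
            )
            for lp in self.layers
        ]
        return replace(
            self,
            factors=self.factors.detached(),
            refiner=ref,
            query_refiner=qref,
            layers=layers,
            W_samp=W_samp,
            readout=ad.data(self.readout),
        )

    def snapshot(self) -> dict:
        return {k: v.data.copy() for k, v in self.tensors().items()}

    def restore(self, snap: dict) -> None:
        for k, v in self.tensors().items():
            v.data[...] = snap[k]

    # -- checkpointing ---------------------------------------------------
    def save(self, path, extra_meta: dict | None = None) -> None:
        arrays = {k: ad.data(v) for k, v in self._all_arrays().items()}
        meta = {
            "version": 1,
            "D": self.D,
            "n_layers": self.n_layers,
            "fusion_weight": self.fusion_weight,
            "temperature": self.temperature,
            "top_k": self.top_k,
            "subgraph_edges": self.subgraph_edges,
            "ablation": {
                "no_gsp": self.ablation.no_gsp,
                "random_query": self.ablation.random_query,
                "no_crr": self.ablation.no_crr,
                "no_phi": self.ablation.no_phi,
            },
            "separate_query_refiner": self.query_refiner is not None,
            "no_crr_identity": self.refiner.identity,
            **(extra_meta or {}),
        }
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    def _all_arrays(self) -> dict:
        out = dict(self.tensors())
        if not out:  # already detached: rebuild the name map from arrays
            det = self
            out = {
                "E_h": det.factors.E_h,
                "E_r": det.factors.E_r,
                "E_t": det.factors.E_t,
                "W_samp": det.W_samp,
                "readout": det.readout,
            }
            for k, v in det.refiner.weights.items():
                out[f"lstm.{k}"] = v
            if det.query_refiner is not None:
                for k, v in det.query_refiner.weights.items():
                    out[f"qlstm.{k}"] = v
            for i, lp in enumerate(det.layers):
                out[f"layer{i}.W"] = lp.W
                out[f"layer{i}.W_alpha"] = lp.W_alpha
                out[f"layer{i}.w_alpha"] = lp.w_alpha
        out["rand_ent"] = self.rand_ent
        out["rand_rel"] = self.rand_rel
        return out

    @classmethod
    def load(cls, path) -> "ModelParams":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            arrays = {k: z[k].copy() for k in z.files if k != "meta"}
        flags = AblationFlags(**meta["ablation"])
        refiner = RelationRefiner(
            {
                k.split(".", 1)[1]: v
                for k, v in arrays.items()
                if k.startswith("lstm.")
            },
            identity=meta.get("no_crr_identity", False),
        )
        qref = None
        if meta.get("separate_query_refiner"):
            qref = RelationRefiner(
                {
                    k.split(".", 1)[1]: v
                    for k, v in arrays.items()
                    if k.startswith("qlstm.")
                },
                identity=meta.get("no_crr_identity", False),
            )
        layers = [
            LayerParams(
                W=arrays[f"layer{i}.W"],
                W_alpha=arrays[f"layer{i}.W_alpha"],
                w_alpha=arrays[f"layer{i}.w_alpha"],
                W_samp=arrays["W_samp"],
            )
            for i in range(meta["n_layers"])
        ]
        return cls(
            factors=CPFactors(arrays["E_h"], arrays["E_r"], arrays["E_t"]),
            refiner=refiner,
            query_refiner=qref,
            layers=layers,
            W_samp=arrays["W_samp"],
            readout=arrays["readout"],
            rand_ent=arrays["rand_ent"],
            rand_rel=arrays["rand_rel"],
            fusion_weight=meta["fusion_weight"],
            temperature=meta["temperature"],
            top_k=meta.get("top_k", 100),
            subgraph_edges=meta["subgraph_edges"],
            ablation=flags,
        )


def init_params(
    n_entities: int,
    n_relations: int,
    D: int,
    n_layers: int,
    seed: int,
    init_scale: float = 0.1,
    fusion_weight: float = 0.7,
    temperature: float = 1.0,
    top_k: int = 100,
    subgraph_edges: str = "all",
    ablation: AblationFlags | None = None,
    separate_query_refiner: bool = False,
    trainable: bool = True,
    avg_degree: float | None = None,
) -> ModelParams:
    """Fresh, seeded parameters (Tensors when ``trainable``).

    ``avg_degree`` (mean outgoing degree of the graph) sets a
    variance-preserving scale for the per-layer message transforms: node
    updates sum over all incoming edges, so without degree-aware scaling
    the tanh pre-activations grow with the neighbourhood size and saturate
    at initialization.
    """
    ablation = ablation or AblationFlags()
    factors = init_factors(n_entities, n_relations, D, seed, init_scale)
    refiner = init_refiner(D, seed + 1)
    refiner.identity = ablation.no_crr
    qref = None
    if separate_query_refiner:
        qref = init_refiner(D, seed + 2)
        qref.identity = ablation.no_crr
    w_scale = 1.0 / np.sqrt(D)
    rng_layers = np.random.default_rng(seed + 3)
    # relevance scoring starts as a copy of the readout: selection then
    # keeps the candidates the readout ranks high, so training-time
    # subgraphs and final ranking agree from the first epoch
    readout = rng_layers.normal(0.0, w_scale, size=(1, D))
    W_samp = readout.copy()
    # small message transforms at initialization: the structural branch
    # starts near zero and grows into an organized regime while the
    # attention and refiner settle; larger starts saturate the tanh stack
    # or lock in disorganized representations (both observed)
    msg_scale = (
        1.0 / (np.sqrt(D) * (1.0 + avg_degree)) if avg_degree else w_scale
    )
    layers = []
    for _ in range(n_layers):
        layers.append(
            LayerParams(
                W=rng_layers.normal(0.0, msg_scale, size=(D, D)),
                W_alpha=rng_layers.normal(0.0, w_scale, size=(D, D)),
                w_alpha=rng_layers.normal(0.0, w_scale, size=D),
                W_samp=W_samp,
            )
        )
    rand_rng = np.random.default_rng(seed + 4)
    rand_ent = rand_rng.normal(0.0, max(init_scale, 1e-3), size=(n_entities, D))
    rand_rel = rand_rng.normal(0.0, max(init_scale, 1e-3), size=(n_relations, D))
    params = ModelParams(
        factors=factors,
        refiner=refiner,
        query_refiner=qref,
        layers=layers,
        W_samp=W_samp,
        readout=readout,
        rand_ent=rand_ent,
        rand_rel=rand_rel,
        fusion_weight=fusion_weight,
        temperature=temperature,
        top_k=top_k,
        subgraph_edges=subgraph_edges,
        ablation=ablation,
    )
    if trainable:
        params = _tensorize(params)
    return params


def _tensorize(params: ModelParams) -> ModelParams:
    t = ad.Tensor
    W_samp = t(ad.data(params.W_samp))
    refiner = RelationRefiner(
        {k: t(ad.data(v)) for k, v in params.refiner.weights.items()},
        params.refiner.identity,
    )
    qref = None
    if params.query_refiner is not None:
        qref = RelationRefiner(
            {k: t(ad.data(v)) for k, v in params.query_refiner.weights.items()},
            params.query_refiner.identity,
        )
    layers = [
        LayerParams(
            W=t(ad.data(lp.W)),
            W_alpha=t(ad.data(lp.W_alpha)),
            w_alpha=t(ad.data(lp.w_alpha)),
            W_samp=W_samp,
        )
        for lp in params.layers
    ]
    return replace(
        params,
        factors=CPFactors(
            t(ad.data(params.factors.E_h)),
            t(ad.data(params.factors.E_r)),
            t(ad.data(params.factors.E_t)),
        ),
        refiner=refiner,
        query_refiner=qref,
        layers=layers,
        W_samp=W_samp,
        readout=t(ad.data(params.readout)),
    )
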