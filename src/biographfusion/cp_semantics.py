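"""Canonical polyadic (CP) factors and the global semantic score.

The knowledge graph's binary adjacency tensor is modelled in factorized
form by three matrices: head-entity embeddings ``E_h`` (|V| x D), relation
embeddings ``E_r`` (|R| x D) and tail-entity embeddings ``E_t`` (|V| x D).
A triple's compatibility is the trilinear product
``phi(h, r, t) = sum_d e_h(d) * e_r(d) * e_t(d)``.  Only factorized scoring
is ever computed; the dense tensor is never materialized.

The N3 penalty (sum of cubed absolute values of the query-entity, refined
query-relation and answer embeddings) is the weighted-nuclear-3-norm
surrogate used to regularize the factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad


@dataclass
class CPFactors:
    """The three CP factor matrices (rows may be Tensors during training)."""

    E_h: object  # (|V|, D)
    E_r: object  # (|R_aug|, D)
    E_t: object  # (|V|, D)

    @property
    def D(self) -> int:
        return ad.data(self.E_h).shape[1]

    @property
    def n_entities(self) -> int:
        return ad.data(self.E_h).shape[0]

    def detached(self) -> "CPFactors":
        return CPFactors(ad.data(self.E_h), ad.data(self.E_r), ad.data(self.E_t))


def init_factors(nV: int, nR: int, D: int, seed: int, scale: float = 0.1) -> CPFactors:
    """I.i.d. zero-mean normal factors with standard deviation ``scale``."""
    if nV < 1 or nR < 1 or D < 1:
        raise ValueError("nV, nR and D must all be >= 1")
    if scale < 0:
        raise ValueError("scale must be non-negative")
    rng = np.random.default_rng(seed)
    return CPFactors(
        E_h=rng.normal(0.0, scale, size=(nV, D)) if scale else np.zeros((nV, D)),
        E_r=rng.normal(0.0, scale, size=(nR, D)) if scale else np.zeros((nR, D)),
        E_t=rng.normal(0.0, scale, size=(nV, D)) if scale else np.zeros((nV, D)),
    )


def cp_score(factors: CPFactors, h: int, r_embedding, t: int):
    """Trilinear compatibility of ``(h, r, t)``.

    ``r_embedding`` is a length-D vector: either a row of ``E_r`` or a
    refined relation embedding, which is how the refined query relation
    enters the semantic branch of the hybrid score.
    """
    e_h = ad.data(factors.E_h)[h]
    e_t = ad.data(factors.E_t)[t]
    if ad.data(r_embedding).shape != e_h.shape:
        raise ValueError(
            f"relation embedding has shape {ad.data(r_embedding).shape}, "
            f"expected {e_h.shape}"
        )
    return float(np.sum(e_h * ad.data(r_embedding) * e_t))


def cp_score_all(factors: CPFactors, qe: int, r_embedding) -> np.ndarray:
    """``cp_score`` against every candidate tail at once (length |V|)."""
    e_h = ad.data(factors.E_h)[qe]
    r = ad.data(r_embedding)
    if r.shape != e_h.shape:
        raise ValueError("relation embedding dimension mismatch")
    return ad.data(factors.E_t) @ (e_h * r)


def n3_penalty(e_qe, e_qr, e_qa):
    """``||e_qe||_3^3 + ||e_qr||_3^3 + ||e_qa||_3^3`` (works on Tensors)."""
    total = 0.0
    for v in (e_qe, e_qr, e_qa):
        total = total + (ad.absolute(v) ** 3).sum()
    return total


def lp_penalty(e_qe, e_qr, e_qa, p: int):
    """L1 (p=1) or squared-L2 (p=2) alternative regularizer."""
    total = 0.0
    for v in (e_qe, e_qr, e_qa):
        total = total + (ad.absolute(v) ** p).sum()
    return total


def save_factors(path, factors: CPFactors, meta: dict | None = None) -> None:
    """Serialize factor matrices with shape metadata (npz container)."""
    import json

    np.savez(
        path,
        E_h=ad.data(factors.E_h),
        E_r=ad.data(factors.E_r),
        E_t=ad.data(factors.E_t),
        meta=np.array(json.dumps({"version": 1, **(meta or {})})),
    )


def load_factors(path) -> CPFactors:
    with np.load(path, allow_pickle=False) as z:
        return CPFactors(z["E_h"].copy(), z["E_r"].copy(), z["E_t"].copy())
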