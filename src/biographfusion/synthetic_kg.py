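"""Synthetic knowledge graphs with the structure the model assumes.

Two generators, kept separate so the semantic and the structural branch
can each be stress-tested in isolation:

* :func:`generate_cp_kg` plants a low-rank CP tensor and emits the
  highest-scoring cells as facts, so a purely semantic (embedding) model
  can recover held-out links;
* :func:`generate_rule_kg` samples random body-relation facts and
  materializes every rule-head triple implied by composing them
  (multi-hop compositional structure), holding out a fraction of the
  rule heads as validation/test queries whose facts are removed from the
  graph — recovering them requires multi-hop reasoning.

Entity names carry biomedical-style prefixes (DIS_/GEN_/CHEM_) purely to
exercise heterogeneous-looking vocabularies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kg_data import write_manifest, write_triples

_RELATION_POOL = ("disease_gene", "gene_chemical", "disease_chemical")
_PREFIXES = ("DIS", "GEN", "CHEM")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic knowledge graph.

    ``rule_set`` is a list of ``(head_relation, [body_relations...])``
    composition rules over base-relation indices; ``density`` is the
    expected number of sampled facts per entity; ``split_fractions`` are
    the train/valid/test proportions (for rule graphs the held-out
    fraction of rule-head triples is valid + test).
    """

    n_entities: int = 50
    n_base_relations: int = 3
    cp_rank: int = 4
    rule_set: list = field(default_factory=lambda: [(2, [0, 1])])
    density: float = 8.0
    noise_rate: float = 0.05
    split_fractions: tuple = (0.7, 0.1, 0.2)
    seed: int = 7
    background_cap: int | None = None

    def __post_init__(self):
        fr = self.split_fractions
        if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must lie in [0, 1)")
        for head, body in self.rule_set:
            if not 1 <= len(body) <= 3:
                raise ValueError("rule bodies must have length 1-3")
            for r in [head, *body]:
                if not 0 <= r < self.n_base_relations:
                    raise ValueError(f"rule references unknown relation {r}")

    def entity_name(self, i: int) -> str:
        prefix = _PREFIXES[(3 * i) // self.n_entities if self.n_entities else 0]
        return f"{prefix}_{i:04d}"

    def relation_name(self, r: int) -> str:
        if r < len(_RELATION_POOL):
            return _RELATION_POOL[r]
        return f"rel_{r}"

    def to_dict(self) -> dict:
        return {
            "n_entities": self.n_entities,
            "n_base_relations": self.n_base_relations,
            "cp_rank": self.cp_rank,
            "rule_set": [[h, list(b)] for h, b in self.rule_set],
            "density": self.density,
            "noise_rate": self.noise_rate,
            "split_fractions": list(self.split_fractions),
            "seed": self.seed,
            "background_cap": self.background_cap,
        }


def planted_factors(spec: SyntheticSpec):
    """The seeded rank-``cp_rank`` factors behind :func:`generate_cp_kg`."""
    rng = np.random.default_rng([spec.seed, 11])
    A = rng.normal(size=(spec.n_entities, spec.cp_rank))
    B = rng.normal(size=(spec.n_base_relations, spec.cp_rank))
    C = rng.normal(size=(spec.n_entities, spec.cp_rank))
    return A, B, C


def generate_cp_kg(spec: SyntheticSpec) -> list:
    """Facts of a planted low-rank tensor: the top-density scoring cells.

    Emits the ``round(density * n_entities)`` cells with the highest
    planted trilinear score (ties broken by cell index), as name triples.
    """
    if spec.cp_rank < 1:
        raise ValueError("cp_rank must be >= 1")
    nE, nR = spec.n_entities, spec.n_base_relations
    n_target = int(round(spec.density * nE))
    total = nE * nR * nE
    if n_target > total:
        raise ValueError(
            f"density {spec.density} asks for {n_target} facts but the graph "
            f"has only {total} cells"
        )
    A, B, C = planted_factors(spec)
    scores = np.einsum("hd,rd,td->hrt", A, B, C).reshape(-1)
    order = np.lexsort((np.arange(total), -scores))
    cells = np.sort(order[:n_target])
    h = cells // (nR * nE)
    r = (cells // nE) % nR
    t = cells % nE
    return [
        (spec.entity_name(int(a)), spec.relation_name(int(b)), spec.entity_name(int(c)))
        for a, b, c in zip(h, r, t)
    ]


def cp_threshold(spec: SyntheticSpec) -> float:
    """Planted-score threshold implied by the requested density."""
    A, B, C = planted_factors(spec)
    scores = np.einsum("hd,rd,td->hrt", A, B, C).reshape(-1)
    n_target = int(round(spec.density * spec.n_entities))
    return float(np.partition(scores, -n_target)[-n_target])


def generate_rule_kg(spec: SyntheticSpec):
    """Compositional-rule graph; returns ``(graph_triples, held_out)``.

    Body facts are sampled uniformly at random; every rule-head triple
    implied by composing them is materialized; a seeded ``valid + test``
    fraction of the rule heads is held out (facts removed from the graph);
    ``noise_rate`` spurious random facts are injected, never colliding
    with a held-out triple.
    """
    rng = np.random.default_rng([spec.seed, 23])
    nE = spec.n_entities
    body_rels = sorted({r for _, body in spec.rule_set for r in body})
    facts: set = set()
    if body_rels:
        n_facts = int(round(spec.density * nE))
        per_rel = max(1, n_facts // len(body_rels))
        for r in body_rels:
            pairs = rng.choice(nE * nE, size=min(per_rel, nE * nE), replace=False)
            for p in np.sort(pairs):
                facts.add((int(p // nE), r, int(p % nE)))
    # materialize every implied rule-head triple
    heads: set = set()
    adj = {r: {} for r in body_rels}
    for h, r, t in facts:
        adj[r].setdefault(h, []).append(t)
    for head_rel, body in spec.rule_set:
        # walk the body chain: reach maps start -> set of chain endpoints
        reach = {e: {e} for e in range(nE)}
        for r in body:
            new_reach = {}
            for start, nodes in reach.items():
                nxt = set()
                for v in nodes:
                    nxt.update(adj[r].get(v, ()))
                if nxt:
                    new_reach[start] = nxt
            reach = new_reach
        for start, nodes in reach.items():
            for end in nodes:
                heads.add((start, head_rel, end))
    heads -= facts
    head_list = sorted(heads)
    rng.shuffle(head_list)
    held_frac = spec.split_fractions[1] + spec.split_fractions[2]
    n_held = int(round(held_frac * len(head_list)))
    held_out = sorted(head_list[:n_held])
    retained = head_list[n_held:]
    graph = facts | set(retained)
    # spurious facts (never leaking a held-out triple)
    n_noise = int(round(spec.noise_rate * len(graph)))
    forbidden = graph | set(held_out)
    added = 0
    while added < n_noise:
        h = int(rng.integers(nE))
        r = int(rng.integers(spec.n_base_relations))
        t = int(rng.integers(nE))
        if (h, r, t) not in forbidden:
            graph.add((h, r, t))
            forbidden.add((h, r, t))
            added += 1
    name = lambda trip: (
        spec.entity_name(trip[0]),
        spec.relation_name(trip[1]),
        spec.entity_name(trip[2]),
    )
    return [name(x) for x in sorted(graph)], [name(x) for x in held_out]


def write_splits(triples, held_out, spec: SyntheticSpec, out_dir) -> dict:
    """Write ``train/valid/test/facts.txt`` plus a JSON manifest.

    Rule graphs: rule-head triples in the graph become training queries,
    all other graph facts are background structure (``facts.txt``), and
    the held-out triples are split into valid/test.  Low-rank graphs
    (no held-out list): the facts themselves are split by the
    train/valid/test fractions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([spec.seed, 31])
    head_names = {spec.relation_name(h) for h, _ in spec.rule_set}
    if held_out:
        train = [t for t in triples if t[1] in head_names]
        background = [t for t in triples if t[1] not in head_names]
        held = list(held_out)
        rng.shuffle(held)
        fr_v, fr_t = spec.split_fractions[1], spec.split_fractions[2]
        n_valid = int(round(len(held) * fr_v / (fr_v + fr_t)))
        valid, test = sorted(held[:n_valid]), sorted(held[n_valid:])
    else:
        pool = list(triples)
        rng.shuffle(pool)
        n = len(pool)
        n_train = int(round(spec.split_fractions[0] * n))
        n_valid = int(round(spec.split_fractions[1] * n))
        train = sorted(pool[:n_train])
        valid = sorted(pool[n_train : n_train + n_valid])
        test = sorted(pool[n_train + n_valid :])
        background = []
    if spec.background_cap is not None and len(background) > spec.background_cap:
        keep = rng.choice(len(background), size=spec.background_cap, replace=False)
        background = [background[i] for i in np.sort(keep)]
    write_triples(out_dir / "train.txt", train)
    write_triples(out_dir / "valid.txt", valid)
    write_triples(out_dir / "test.txt", test)
    write_triples(out_dir / "facts.txt", background)
    manifest = {
        "spec": spec.to_dict(),
        "counts": {
            "train": len(train),
            "valid": len(valid),
            "test": len(test),
            "facts": len(background),
        },
        "relation_layout": "base [0,n), inverse [n,2n), identity 2n",
        "files": ["train.txt", "valid.txt", "test.txt", "facts.txt"],
    }
    write_manifest(out_dir / "manifest.json", manifest)
    return manifest
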