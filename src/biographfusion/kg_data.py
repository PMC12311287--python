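"""Multi-relational triple stores with reverse/identity augmentation.

A knowledge graph is a set of ``(head, relation, tail)`` facts over entity
and relation vocabularies.  Facts are augmented with one inverse fact per
base fact and one identity self-loop per entity, so that query-guided
propagation can walk edges in either direction and carry a node's state
forward through its own self-loop.

Relation index layout: base relations occupy ``[0, n)``, inverses
``[n, 2n)`` (inverse of ``r`` is ``r + n``) and the single identity
relation has index ``2n``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

IDENTITY_NAME = "<identity>"


class Triple(NamedTuple):
    """One fact ``(head, relation, tail)`` as 0-based integer indices."""

    head: int
    relation: int
    tail: int


class ParseError(ValueError):
    """Raised for malformed triple files (reports the offending line)."""


@dataclass(frozen=True)
class Vocabulary:
    """Bijections between entity / base-relation names and indices."""

    entity_names: tuple
    relation_names: tuple
    entity_index: dict = field(repr=False, default=None)
    relation_index: dict = field(repr=False, default=None)

    def __post_init__(self):
        if self.entity_index is None:
            object.__setattr__(
                self, "entity_index", {n: i for i, n in enumerate(self.entity_names)}
            )
        if self.relation_index is None:
            object.__setattr__(
                self,
                "relation_index",
                {n: i for i, n in enumerate(self.relation_names)},
            )

    @property
    def n_entities(self) -> int:
        return len(self.entity_names)

    @property
    def n_base_relations(self) -> int:
        return len(self.relation_names)

    @property
    def n_relations_augmented(self) -> int:
        return 2 * self.n_base_relations + 1

    def augmented_relation_name(self, idx: int) -> str:
        n = self.n_base_relations
        if idx < n:
            return self.relation_names[idx]
        if idx < 2 * n:
            return self.relation_names[idx - n] + "^-1"
        if idx == 2 * n:
            return IDENTITY_NAME
        raise IndexError(f"relation index {idx} out of range")


@dataclass
class KnowledgeGraph:
    """Augmented triple store with a CSR outgoing-edge index.

    ``facts`` holds the augmented structural edges used for propagation;
    ``query_splits`` holds the (non-augmented) train/valid/test query triples.
    """

    vocab: Vocabulary
    facts: np.ndarray  # (F, 3) int64, lexicographically sorted, unique
    n_base_relations: int
    query_splits: dict = field(default_factory=dict)
    _indptr: np.ndarray = field(default=None, repr=False)
    _fact_set: frozenset = field(default=None, repr=False)

    def __post_init__(self):
        self.facts = np.asarray(self.facts, dtype=np.int64).reshape(-1, 3)
        order = np.lexsort((self.facts[:, 2], self.facts[:, 1], self.facts[:, 0]))
        self.facts = np.unique(self.facts[order], axis=0)
        heads = self.facts[:, 0]
        self._indptr = np.searchsorted(
            heads, np.arange(self.vocab.n_entities + 1)
        ).astype(np.int64)

    # -- basic views -----------------------------------------------------
    @property
    def n_entities(self) -> int:
        return self.vocab.n_entities

    @property
    def n_relations(self) -> int:
        """Number of relations after augmentation (2n + 1)."""
        return 2 * self.n_base_relations + 1

    @property
    def identity_relation(self) -> int:
        return 2 * self.n_base_relations

    @property
    def fact_set(self) -> frozenset:
        if self._fact_set is None:
            self._fact_set = frozenset(map(tuple, self.facts.tolist()))
        return self._fact_set

    def has_fact(self, h: int, r: int, t: int) -> bool:
        return (h, r, t) in self.fact_set

    def outgoing(self, nodes: Iterable[int]) -> np.ndarray:
        """All facts whose head is in ``nodes``; sorted by (head, rel, tail)."""
        nodes = np.unique(np.fromiter(nodes, dtype=np.int64, count=-1))
        if nodes.size and (nodes.min() < 0 or nodes.max() >= self.n_entities):
            raise IndexError("node index out of range")
        starts = self._indptr[nodes]
        stops = self._indptr[nodes + 1]
        counts = stops - starts
        total = int(counts.sum())
        if total == 0:
            return np.empty((0, 3), dtype=np.int64)
        # vectorized range concatenation
        idx = np.repeat(stops - counts.cumsum(), counts) + np.arange(total)
        return self.facts[idx]

    # -- queries ---------------------------------------------------------
    def split_queries(self, split: str, include_inverse: bool = False) -> np.ndarray:
        """Query triples ``(qe, qr, qa)`` of a split, optionally + inverses."""
        q = np.asarray(self.query_splits[split], dtype=np.int64).reshape(-1, 3)
        if include_inverse and len(q):
            inv = np.stack(
                [q[:, 2], q[:, 1] + self.n_base_relations, q[:, 0]], axis=1
            )
            q = np.concatenate([q, inv], axis=0)
        return q

    def known_answers(self) -> dict:
        """Map ``(qe, qr) -> set of answers`` over all splits (and inverses).

        This is the filter set for filtered ranking: every tail known to be
        true for the pair in train, valid or test, in either direction.
        """
        known: dict = {}
        n = self.n_base_relations
        for split in self.query_splits:
            for h, r, t in self.split_queries(split).tolist():
                known.setdefault((h, r), set()).add(t)
                known.setdefault((t, r + n), set()).add(h)
        return known


# -- construction ---------------------------------------------------------


def read_triples(path) -> list:
    """Read a UTF-8, tab-separated triple file; returns name triples in order."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            out.append(tuple(parts))
    return out


def write_triples(path, triples: Sequence) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h, r, t in triples:
            fh.write(f"{h}\t{r}\t{t}\n")


def build_vocab(raw_triples: Iterable) -> Vocabulary:
    """Sorted, deduplicated entity/relation vocabularies from name triples."""
    entities, relations = set(), set()
    for h, r, t in raw_triples:
        entities.add(h)
        entities.add(t)
        relations.add(r)
    return Vocabulary(tuple(sorted(entities)), tuple(sorted(relations)))


def encode_triples(raw: Iterable, vocab: Vocabulary) -> np.ndarray:
    """Map name triples to an ``(n, 3)`` index array (KeyError if unknown)."""
    rows = []
    for h, r, t in raw:
        try:
            rows.append(
                (vocab.entity_index[h], vocab.relation_index[r], vocab.entity_index[t])
            )
        except KeyError as exc:
            raise KeyError(f"unknown name {exc.args[0]!r} in triple ({h}, {r}, {t})")
    return np.asarray(rows, dtype=np.int64).reshape(-1, 3)


def augment_graph(raw_facts: Iterable, vocab: Vocabulary) -> KnowledgeGraph:
    """Build a :class:`KnowledgeGraph` with inverse and identity facts.

    ``|facts| = 2 * |unique base facts| + |V|``: one inverse per base fact
    plus one identity self-loop per entity.
    """
    base = np.unique(encode_triples(raw_facts, vocab), axis=0)
    n = vocab.n_base_relations
    inverse = (
        np.stack([base[:, 2], base[:, 1] + n, base[:, 0]], axis=1)
        if len(base)
        else np.empty((0, 3), dtype=np.int64)
    )
    ids = np.arange(vocab.n_entities, dtype=np.int64)
    identity = np.stack([ids, np.full_like(ids, 2 * n), ids], axis=1)
    facts = np.concatenate([base, inverse, identity], axis=0)
    return KnowledgeGraph(vocab=vocab, facts=facts, n_base_relations=n)


def outgoing_edges(kg: KnowledgeGraph, nodes: Iterable[int]) -> list:
    """Facts with head in ``nodes`` as :class:`Triple` objects, sorted."""
    return [Triple(*row) for row in kg.outgoing(nodes).tolist()]


def load_dataset(directory) -> KnowledgeGraph:
    """Load ``train/valid/test.txt`` (+ optional ``facts.txt``) from a folder.

    The vocabulary is built from the union of all files (transductive
    setting); the structural graph is augmented from train + background
    facts only, so held-out queries never leak edges.
    """
    directory = Path(directory)
    splits = {}
    for name in ("train", "valid", "test"):
        path = directory / f"{name}.txt"
        splits[name] = read_triples(path) if path.exists() else []
    background = (
        read_triples(directory / "facts.txt")
        if (directory / "facts.txt").exists()
        else []
    )
    vocab = build_vocab(
        [t for s in splits.values() for t in s] + list(background)
    )
    kg = augment_graph(list(splits["train"]) + list(background), vocab)
    kg.query_splits = {
        name: encode_triples(raw, vocab) for name, raw in splits.items()
    }
    return kg


def write_manifest(path, payload: dict) -> None:
    """Write a small JSON run manifest (file paths, counts, layout)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
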