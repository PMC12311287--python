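import numpy as np
import pytest

from biographfusion import kg_data
from biographfusion import synthetic_kg as sk


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_raw_triples():
    """Small hand-written name triples: a 4-entity, 2-relation graph."""
    return [
        ("D1", "disease_gene", "G1"),
        ("D1", "disease_gene", "G2"),
        ("G1", "gene_chemical", "C1"),
        ("G2", "gene_chemical", "C1"),
        ("D1", "disease_chemical", "C1"),
    ]


@pytest.fixture
def toy_kg(toy_raw_triples):
    vocab = kg_data.build_vocab(toy_raw_triples)
    kg = kg_data.augment_graph(toy_raw_triples, vocab)
    enc = kg_data.encode_triples(toy_raw_triples, vocab)
    kg.query_splits = {"train": enc[:3], "valid": enc[3:4], "test": enc[4:]}
    return kg


@pytest.fixture(scope="session")
def rule_kg_dir(tmp_path_factory):
    """A small compositional-rule KG written to disk once per session."""
    spec = sk.SyntheticSpec(
        n_entities=20, density=4.0, noise_rate=0.0, seed=11
    )
    triples, held = sk.generate_rule_kg(spec)
    out = tmp_path_factory.mktemp("rulekg")
    sk.write_splits(triples, held, spec, out)
    return out


@pytest.fixture(scope="session")
def rule_kg(rule_kg_dir):
    return kg_data.load_dataset(rule_kg_dir)
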