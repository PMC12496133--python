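import numpy as np
import pandas as pd
import pytest

from pathact.pathway_io import Entity, Interaction, PathwayNetwork


def network_from_edges(proteins, edges, complexes=(), families=()):
    """Compact builder: edges as (src, tgt, relation) triples."""
    entities = {p: Entity(p, "protein") for p in proteins}
    for c in complexes:
        entities[c] = Entity(c, "complex")
    for f in families:
        entities[f] = Entity(f, "family")
    interactions = [Interaction(s, t, r) for s, t, r in edges]
    return PathwayNetwork(entities=entities, interactions=interactions)


@pytest.fixture
def chain3():
    """A -> B -> C protein-activation chain."""
    return network_from_edges(
        ["A", "B", "C"],
        [("A", "B", "protein-activate"), ("B", "C", "protein-activate")],
    )


@pytest.fixture
def complex_net():
    """Complex CX with components A and B; family FM with members A, C."""
    return network_from_edges(
        ["A", "B", "C"],
        [
            ("A", "CX", "component"),
            ("B", "CX", "component"),
            ("A", "FM", "member"),
            ("C", "FM", "member"),
        ],
        complexes=["CX"],
        families=["FM"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def ternary_frame(values, genes, samples):
    return pd.DataFrame(values, index=genes, columns=samples, dtype=float)
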