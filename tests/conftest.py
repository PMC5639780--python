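import numpy as np
import pandas as pd
import pytest

from hierdag import OntologyDAG, SyntheticSpec, compute_levels, generate_instance


@pytest.fixture
def chain_dag():
    """root → a → b."""
    return OntologyDAG.from_edges([("root", "a"), ("a", "b")])


@pytest.fixture
def diamond_dag():
    """root → {a, b} → c, plus shortcut root → c (max level of c is 2)."""
    return OntologyDAG.from_edges(
        [("root", "a"), ("root", "b"), ("a", "c"), ("b", "c"), ("root", "c")]
    )


def random_dag(rng: np.random.Generator, n_terms: int, p_extra: float = 0.3):
    """Small random rooted DAG: term i may attach to any earlier term."""
    terms = [f"t{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        parent = terms[rng.integers(i)]
        edges.append((parent, terms[i]))
        for j in range(i):
            if terms[j] != parent and rng.random() < p_extra / max(i, 1):
                edges.append((terms[j], terms[i]))
    return OntologyDAG.from_edges(edges, extra_terms=terms)


def random_scores(rng: np.random.Generator, dag: OntologyDAG, n_genes: int):
    genes = [f"g{i}" for i in range(n_genes)]
    values = rng.random((n_genes, len(dag.terms)))
    return pd.DataFrame(values, index=genes, columns=dag.terms)


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


@pytest.fixture(scope="session")
def small_instance():
    """A medium synthetic instance shared by read-only tests."""
    spec = SyntheticSpec(n_terms=80, n_genes=60, n_levels=5,
                         mean_annotations_per_gene=3.0, seed=7)
    return generate_instance(spec)
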