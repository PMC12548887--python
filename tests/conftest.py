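import networkx as nx
import numpy as np
import pytest

from cohortnet.synthetic import (
    CohortSpec,
    LayerSpec,
    PlantedChain,
    generate_cohort,
)


@pytest.fixture
def fig1_network():
    """Three-node signed network of the published Boolean worked example:
    B (active) inhibits A with weight -0.3, C (active) activates A with
    weight +0.5."""
    g = nx.Graph()
    g.add_edge("B", "A", weight=-0.3)
    g.add_edge("C", "A", weight=0.5)
    return g


@pytest.fixture
def small_cohort():
    """Complete (no missingness) two-layer cohort with one strong block."""
    layers = (
        LayerSpec("alpha", n_continuous=4, block_size=3, n_blocks=1,
                  block_loading=0.8),
        LayerSpec("beta", n_continuous=3, n_binary=1),
    )
    spec = CohortSpec(n_subjects=400, layers=layers, seed=11)
    return spec, generate_cohort(spec)


@pytest.fixture
def chain_cohort_spec():
    """Three-layer cohort with a planted chain ending in the phenotype layer."""
    layers = (
        LayerSpec("genetic", n_continuous=4, missing_prob=0.05),
        LayerSpec("PET", n_continuous=4, missing_prob=0.1),
        LayerSpec("phenotype", n_continuous=4),
    )
    chain = PlantedChain(("genetic_000", "PET_000", "phenotype_000"), strength=0.8)
    return CohortSpec(n_subjects=800, layers=layers, chains=(chain,), seed=5)


def random_weighted_graph(rng: np.random.Generator, n_nodes: int, p: float,
                          signed: bool = False) -> nx.Graph:
    """Erdos-Renyi graph with positive (or signed) weights, for oracles."""
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n_nodes))
    nodes = list(g.nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                w = rng.uniform(0.1, 1.0)
                if signed and rng.random() < 0.5:
                    w = -w
                g.add_edge(nodes[i], nodes[j], weight=w, length=1.0 / abs(w))
    return g
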