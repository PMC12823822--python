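import numpy as np
import pytest

from kg2ml.graph import EdgeRecord, NodeRecord, PropertyGraph
from kg2ml.simulate import KGSimSpec

NODE_TYPES = ("Disease", "Compound", "Gene", "EFO", "Protein")


def random_typed_graph(rng: np.random.Generator, n_nodes: int = 40,
                       edge_prob: float = 0.08) -> PropertyGraph:
    """Random typed graph for oracle comparisons; guaranteed >=1 disease."""
    types = [rng.choice(NODE_TYPES) for _ in range(n_nodes - 1)] + ["Disease"]
    nodes = [NodeRecord(f"N{i:03d}", t, f"node {i}") for i, t in enumerate(types)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append(EdgeRecord(f"N{i:03d}", f"N{j:03d}", "rel", ""))
    return PropertyGraph.from_records(nodes, edges)


@pytest.fixture
def toy_metapath_graph() -> PropertyGraph:
    """D-C-G1 plus G1-E-G2: one positive, one unlabeled, one feature EFO."""
    nodes = [
        NodeRecord("D1", "Disease", "disease"),
        NodeRecord("C1", "Compound", "compound"),
        NodeRecord("G1", "Gene", "gene 1"),
        NodeRecord("G2", "Gene", "gene 2"),
        NodeRecord("E1", "EFO", "efo"),
    ]
    edges = [
        EdgeRecord("D1", "C1", "r", ""),
        EdgeRecord("C1", "G1", "r", ""),
        EdgeRecord("G1", "E1", "r", ""),
        EdgeRecord("E1", "G2", "r", ""),
    ]
    return PropertyGraph.from_records(nodes, edges)


@pytest.fixture
def small_sim_spec() -> KGSimSpec:
    """Small planted-truth KG spec for fast pipeline-level tests."""
    return KGSimSpec(n_genes=600, n_compounds=40, n_labeled_positive=120,
                     n_signal_efo=20, n_background_efo=60, true_alpha=0.3,
                     seed=7)
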