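import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from phytofp.molgraph import FeatureVocab, smiles_to_graph
from phytofp.synthetic import (
    DEFAULT_FAMILIES,
    GeneratorSpec,
    generate_labelled_molecules,
)

# the 3-family, 300-molecule classification task used across classifier tests
THREE_FAMILIES = (DEFAULT_FAMILIES[0], DEFAULT_FAMILIES[2], DEFAULT_FAMILIES[3])


@pytest.fixture(scope="session")
def three_family_task():
    """300 labelled molecules from 3 graph-separable scaffold families."""
    spec = GeneratorSpec(seed=11, scaffold_families=THREE_FAMILIES,
                         family_weights=(1.0, 1.0, 1.0))
    molecules, ledger = generate_labelled_molecules(spec, n_per_family=100)
    graphs = [smiles_to_graph(m.smiles, m.name) for m in molecules]
    labels = [m.superclass for m in molecules]
    vocab = FeatureVocab.fit(graphs)
    return molecules, graphs, labels, vocab


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def permute_graph(graph, perm):
    """Relabel a MoleculeGraph's atoms by ``perm`` (new index i holds old
    atom perm[i])."""
    from phytofp.molgraph import MoleculeGraph

    inv = np.argsort(perm)
    g = MoleculeGraph(
        name=graph.name + "-permuted",
        nodes=[graph.nodes[perm[i]] for i in range(graph.n_nodes)],
        edges=[(int(inv[i]), int(inv[j])) for i, j in graph.edges],
        edge_features=list(graph.edge_features),
        smiles=graph.smiles,
    )
    g.validate()
    return g
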