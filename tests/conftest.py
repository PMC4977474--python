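import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from coexnet.io import ExpressionMatrix
from coexnet.simulate import generate_modular_dataset

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples; g1 and g2 co-vary, g3 anti-correlates."""
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array([
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.1, 5.9, 8.2],
            [4.0, 3.0, 2.0, 1.0],
        ]),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """The standard planted-module dataset: 2x20 module genes, 360 background."""
    return generate_modular_dataset(
        n_modules=2, module_size=20, n_background=360,
        n_samples=8, noise_sd=0.2, seed=7,
    )


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})


@pytest.fixture
def graph_factory():
    return random_graph
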