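import networkx as nx
import numpy as np
import pytest

from sdanet import ExpressionMatrix


def random_weighted_graph(
    rng: np.random.Generator,
    n: int,
    p: float = 0.35,
    min_component: int = 1,
    node_w: tuple[float, float] = (0.0, 2.0),
    edge_w: tuple[float, float] = (0.0, 1.0),
) -> nx.Graph:
    """Random ER graph with uniform node/edge weights and string ids."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if max(len(c) for c in nx.connected_components(g)) >= min_component:
            break
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
    for nd in g.nodes:
        g.nodes[nd]["weight"] = float(rng.uniform(*node_w))
    for u, v in g.edges:
        g.edges[u, v]["weight"] = float(rng.uniform(*edge_w))
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    """4 genes x 6 samples (3 normal, 3 tumour) with known structure."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],  # identical in both groups
            [1.0, 2.0, 3.0, 2.0, 3.0, 4.0],  # tumour = normal + 1
            [5.0, 5.5, 6.0, 8.0, 7.5, 9.0],  # up in tumour
            [4.0, 3.0, 5.0, 1.0, 2.0, 1.5],  # down in tumour
        ]
    )
    return ExpressionMatrix(
        gene_ids=["gA", "gB", "gC", "gD"],
        values=values,
        sample_groups=["normal"] * 3 + ["tumour"] * 3,
    )
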