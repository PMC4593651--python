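import networkx as nx
import pytest

from starnet import AttributeMap


@pytest.fixture
def five_cycle() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a")])
    return g


@pytest.fixture
def k4() -> nx.Graph:
    return nx.complete_graph(["a", "b", "c", "d"])


@pytest.fixture
def two_group_path():
    """Path a-h-b with a, b in one group and the hub h in another."""
    g = nx.Graph()
    g.add_edges_from([("a", "h"), ("h", "b")])
    attrs = AttributeMap({"a": 1, "b": 1, "h": 2}, ("G1", "G2"))
    return g, attrs


def random_graph(n: int, p: float, seed: int, directed: bool = False) -> nx.Graph:
    """Seeded G(n, p) with string labels, shared by oracle tests."""
    g = nx.gnp_random_graph(n, p, seed=seed, directed=directed)
    return nx.relabel_nodes(g, {v: f"v{v:02d}" for v in g.nodes})


def random_codes(vertices, n_groups: int, seed: int) -> dict[str, int]:
    import numpy as np

    rng = np.random.default_rng(seed)
    vs = sorted(vertices)
    # guarantee every code 1..n_groups appears so codes stay contiguous
    codes = list(range(1, n_groups + 1)) * (len(vs) // n_groups + 1)
    picks = rng.permutation(len(vs))
    return {v: codes[picks[i]] for i, v in enumerate(vs)}
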