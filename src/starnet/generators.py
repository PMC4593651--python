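"""Random-graph generators and synthetic attributed fixtures.

The classical ensembles (Erdos-Renyi G(n, p), Barabasi-Albert
preferential attachment, Watts-Strogatz rewired ring lattice) are
delegated to networkx and relabelled to the package's string-vertex
convention.  The ER density default ``p = 10194 / (351 * 350)`` matches
a 351-vertex network with 5097 unique undirected edges counted once per
direction (symmetric-arc convention), the calibration used throughout
for comparisons against the macaque cortical network.

Two fixture builders support deterministic testing of the attribute
measures: a planted hub neighbourhood with an exact, known star value,
and a stochastic block graph with group-dependent edge densities.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np

from .io import AttributeMap

__all__ = [
    "DEFAULT_ER_P",
    "erdos_renyi",
    "barabasi_albert",
    "watts_strogatz",
    "generate",
    "planted_neighborhood",
    "attributed_block_graph",
]

#: symmetric-arc density of the 351-vertex reference calibration
DEFAULT_ER_P = 10194 / (351 * 350)


def _relabel(g: nx.Graph, directed: bool = False) -> nx.Graph:
    """Copy with zero-padded string ids so lexicographic = numeric order."""
    width = max(4, len(str(max(g.number_of_nodes() - 1, 0))))
    mapping = {v: f"v{int(v):0{width}d}" for v in g.nodes}
    out = nx.DiGraph() if directed else nx.Graph()
    out.add_nodes_from(mapping[v] for v in g.nodes)
    out.add_edges_from((mapping[u], mapping[v]) for u, v in g.edges() if u != v)
    return out


def erdos_renyi(n: int = 351, p: float = DEFAULT_ER_P, seed: int | None = None) -> nx.Graph:
    """G(n, p): each vertex pair linked independently with probability p."""
    if n < 3 or not 0 <= p <= 1:
        raise ValueError("need n >= 3 and p in [0, 1]")
    return _relabel(nx.gnp_random_graph(n, p, seed=seed))


def barabasi_albert(n: int = 351, m: int = 15, seed: int | None = None) -> nx.Graph:
    """Preferential attachment adding ``m`` edges per new vertex."""
    if not 1 <= m < n:
        raise ValueError("need 1 <= edges-per-step < n")
    return _relabel(nx.barabasi_albert_graph(n, m, seed=seed))


def watts_strogatz(
    n: int = 351, k: int = 29, p_rewire: float = 0.4, seed: int | None = None
) -> nx.Graph:
    """Ring lattice with ``k`` nearest neighbours, each edge rewired with
    probability ``p_rewire`` avoiding self-loops and duplicates."""
    if k >= n or not 0 <= p_rewire <= 1:
        raise ValueError("need lattice degree < n and rewiring probability in [0, 1]")
    return _relabel(nx.watts_strogatz_graph(n, k, p_rewire, seed=seed))


def generate(family: str, n: int, seed: int | None = None, **params) -> nx.Graph:
    """Dispatch on family name: ``er`` (p), ``ba`` (m), ``ws`` (k, p_rewire)."""
    family = family.lower()
    if family in ("er", "erdos-renyi"):
        return erdos_renyi(n, params.get("p", DEFAULT_ER_P), seed)
    if family in ("ba", "barabasi-albert"):
        return barabasi_albert(n, params.get("m", 15), seed)
    if family in ("ws", "watts-strogatz"):
        return watts_strogatz(n, params.get("k", 29), params.get("p_rewire", 0.4), seed)
    raise ValueError(f"unknown generator family {family!r}")


def planted_neighborhood(k: int, m: int, seed: int | None = None) -> nx.Graph:
    """Hub joined to ``k`` spokes with exactly ``m`` intra-spoke edges.

    The hub's star value is ``1 - (2 m + k) / k**2`` by construction;
    the ``m`` spoke pairs to connect are chosen uniformly at random.
    """
    max_m = k * (k - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"m must be in [0, {max_m}] for k={k}")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    spokes = [f"s{i:03d}" for i in range(k)]
    g.add_edges_from(("hub", s) for s in spokes)
    pairs = list(combinations(spokes, 2))
    for idx in rng.choice(len(pairs), size=m, replace=False) if m else []:
        g.add_edge(*pairs[idx])
    return g


def attributed_block_graph(
    group_sizes: list[int],
    p_intra: float = 0.5,
    p_inter: float = 0.05,
    seed: int | None = None,
    directed: bool = False,
) -> tuple[nx.Graph, AttributeMap]:
    """Stochastic block graph with per-block Bernoulli edges.

    Vertices of group ``g`` (1-based) are named ``g<g>_v<i>``; each
    within-group pair is linked with probability ``p_intra`` and each
    between-group pair with ``p_inter`` (each ordered pair independently
    when ``directed``).
    """
    if not (0 <= p_intra <= 1 and 0 <= p_inter <= 1):
        raise ValueError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    net = nx.DiGraph() if directed else nx.Graph()
    codes: dict[str, int] = {}
    for g, size in enumerate(group_sizes, start=1):
        for i in range(size):
            v = f"g{g}_v{i:03d}"
            net.add_node(v)
            codes[v] = g
    vertices = sorted(net.nodes)
    pairs = (
        [(u, v) for u in vertices for v in vertices if u != v]
        if directed
        else list(combinations(vertices, 2))
    )
    for u, v in pairs:
        p = p_intra if codes[u] == codes[v] else p_inter
        if rng.random() < p:
            net.add_edge(u, v)
    labels = tuple(f"G{g}" for g in range(1, len(group_sizes) + 1))
    return net, AttributeMap(codes, labels)
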