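"""Null models: isomorph (ISO), degree-preserving edge-swap (MS), and
block-constrained edge-swap (B-MS) randomizations.

ISO permutes vertex labels uniformly, preserving every topological
invariant while shuffling which attribute sits on which topological
position.  MS applies Maslov-Sneppen double-edge swaps, preserving each
vertex's degree (in- and out-degree separately for digraphs) but freeing
everything else.  B-MS restricts the swaps so that both replaced edges
lie in the same attribute block (the same unordered group pair),
additionally preserving the edge count between and within every pair of
groups, and in fact each vertex's per-block degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import AttributeMap

logger = logging.getLogger(__name__)

__all__ = ["RewireConfig", "iso_null", "ms_rewire", "bms_rewire"]


@dataclass(frozen=True)
class RewireConfig:
    """Swap-budget configuration for edge-swap nulls.

    ``swap_multiplier`` successful swaps per edge are attempted (10 by
    default, common practice for Maslov-Sneppen randomization), giving
    up after ``attempt_multiplier`` x edges proposals.
    """

    seed: int | None = None
    swap_multiplier: float = 10.0
    attempt_multiplier: float = 100.0

    def __post_init__(self) -> None:
        if self.swap_multiplier <= 0 or self.attempt_multiplier <= 0:
            raise ValueError("swap/attempt multipliers must be positive")


def iso_null(
    net: nx.Graph, attrs: AttributeMap | None = None, cfg: RewireConfig | None = None
) -> tuple[nx.Graph, AttributeMap | None]:
    """Uniformly random vertex permutation of ``net``.

    The returned network is isomorphic to the input, so every purely
    topological quantity (degree distribution, star-value multiset,
    path lengths) is preserved exactly; the attribute map is returned
    unchanged, so which attribute value sits on which topological role
    is randomized.
    """
    cfg = cfg or RewireConfig()
    rng = np.random.default_rng(cfg.seed)
    vertices = sorted(net.nodes)
    perm = dict(zip(vertices, (vertices[i] for i in rng.permutation(len(vertices)))))
    out = nx.DiGraph() if net.is_directed() else nx.Graph()
    out.add_nodes_from(vertices)
    out.add_edges_from((perm[u], perm[v]) for u, v in net.edges())
    return out, attrs


def _swap_edges(
    G: nx.Graph,
    edges: list[tuple[str, str]],
    rng: np.random.Generator,
    n_target: int,
    n_cap: int,
    allow_flip: bool,
) -> int:
    """In-place double-edge swaps restricted to ``edges``.

    Each accepted swap replaces edges ``(a,b), (c,d)`` with
    ``(a,d), (c,b)``; proposals creating self-loops or parallel edges
    are rejected.  ``allow_flip`` randomly reverses the second edge
    first, needed for undirected unconstrained swaps to reach both
    re-pairings; it must be off for directed arcs and for bipartite
    (inter-group) blocks where each tuple is oriented (group-g end,
    group-h end).
    """
    n_edges = len(edges)
    if n_edges < 2:
        return 0
    swaps = 0
    attempts = 0
    while swaps < n_target and attempts < n_cap:
        attempts += 1
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if allow_flip and rng.integers(0, 2):
            c, d = d, c
        if a == d or c == b or G.has_edge(a, d) or G.has_edge(c, b):
            continue
        G.remove_edge(*edges[i])
        G.remove_edge(*edges[j])
        G.add_edge(a, d)
        G.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        swaps += 1
    if swaps < n_target:
        logger.warning(
            "edge swapping: attempt cap reached after %d/%d successful swaps", swaps, n_target
        )
    return swaps


def ms_rewire(net: nx.Graph, cfg: RewireConfig | None = None) -> nx.Graph:
    """Degree-preserving Maslov-Sneppen randomization.

    Undirected swaps preserve each vertex's degree; directed swaps
    ``(a->b, c->d) -> (a->d, c->b)`` preserve in- and out-degrees
    separately.  Requires at least two edges.
    """
    if net.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to rewire")
    cfg = cfg or RewireConfig()
    rng = np.random.default_rng(cfg.seed)
    out = net.copy()
    edges = sorted(out.edges())
    m = len(edges)
    _swap_edges(
        out,
        edges,
        rng,
        n_target=int(cfg.swap_multiplier * m),
        n_cap=int(cfg.attempt_multiplier * m),
        allow_flip=not out.is_directed(),
    )
    return out


def _block_key(attrs: AttributeMap, u: str, v: str, directed: bool) -> tuple[int, int]:
    gu, gv = attrs[u], attrs[v]
    if directed:
        return (gu, gv)  # arc classes are ordered group pairs
    return (gu, gv) if gu <= gv else (gv, gu)


def bms_rewire(net: nx.Graph, attrs: AttributeMap, cfg: RewireConfig | None = None) -> nx.Graph:
    """Block-constrained Maslov-Sneppen randomization.

    Swaps run independently inside each attribute block (the edges
    joining one unordered pair of groups, or lying within one group), so
    the per-block edge counts are preserved exactly alongside the degree
    sequence.  Inter-group blocks use bipartite-safe swaps: every
    endpoint stays in its own group.  For digraphs, arcs are grouped by
    ordered group pair so arc directions between groups are preserved
    too.
    """
    if net.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to rewire")
    attrs.validate(net)
    cfg = cfg or RewireConfig()
    rng = np.random.default_rng(cfg.seed)
    out = net.copy()
    directed = out.is_directed()
    blocks: dict[tuple[int, int], list[tuple[str, str]]] = {}
    for u, v in sorted(out.edges()):
        key = _block_key(attrs, u, v, directed)
        if not directed and attrs[u] != attrs[v] and attrs[u] != key[0]:
            u, v = v, u  # orient inter-group edges as (low-group end, high-group end)
        blocks.setdefault(key, []).append((u, v))
    for key in sorted(blocks):
        edges = blocks[key]
        m = len(edges)
        intra = key[0] == key[1]
        _swap_edges(
            out,
            edges,
            rng,
            n_target=int(cfg.swap_multiplier * m),
            n_cap=int(cfg.attempt_multiplier * m),
            allow_flip=intra and not directed,
        )
    return out
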