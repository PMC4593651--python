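"""Attribute-space analysis: disparity and workload closure.

These measures treat a vertex attribute (e.g. brain super-area
membership, coded ``1..K``) as a partition of the network into groups and
ask how local subnetworks and groups behave relative to it.  They are
defined on undirected networks.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .io import AttributeMap
from .star import star_value_undirected

__all__ = [
    "disparity",
    "disparity_profile",
    "open_pairs_in_group",
    "wcc",
    "wcc_table",
]


def disparity(net: nx.Graph, attrs: AttributeMap, v: str) -> int:
    """Number of distinct spoke group codes differing from the hub's.

    0 means the hub and all its spokes share one group (homogeneous
    neighbourhood); the maximum is ``K - 1``.  Undefined (ValueError) for
    isolated vertices.
    """
    if net.is_directed():
        raise ValueError("disparity is defined on undirected networks")
    spokes = list(net.neighbors(v))
    if not spokes:
        raise ValueError(f"vertex {v!r} is isolated: disparity undefined")
    return len({attrs[s] for s in spokes} - {attrs[v]})


def disparity_profile(net: nx.Graph, attrs: AttributeMap) -> pd.DataFrame:
    """Per-disparity summary of all local subnetworks.

    For each disparity value ``d`` present: the mean hub star value, the
    mean hub degree, and the fraction of local subnetworks at that
    disparity (fractions sum to 1).  Isolated vertices are excluded.
    """
    attrs.validate(net)
    rows: dict[int, list[tuple[float, int]]] = {}
    for v in sorted(net.nodes):
        if net.degree(v) == 0:
            continue
        d = disparity(net, attrs, v)
        rows.setdefault(d, []).append((star_value_undirected(net, v), net.degree(v)))
    total = sum(len(r) for r in rows.values())
    return pd.DataFrame(
        {
            "disparity": sorted(rows),
            "mean_sv": [float(np.mean([sv for sv, _ in rows[d]])) for d in sorted(rows)],
            "mean_degree": [float(np.mean([k for _, k in rows[d]])) for d in sorted(rows)],
            "fraction": [len(rows[d]) / total for d in sorted(rows)],
        }
    )


def open_pairs_in_group(net: nx.Graph, attrs: AttributeMap, g: int) -> set[frozenset[str]]:
    """Non-adjacent same-group spoke pairs sharing at least one hub.

    A pair ``{a, b}`` with both vertices in group ``g`` qualifies when
    ``a`` and ``b`` are not adjacent but have a common neighbour anywhere
    in the network (the common hub may belong to any group).
    """
    if net.is_directed():
        raise ValueError("workload closure is defined on undirected networks")
    if g not in set(attrs.codes.values()):
        raise ValueError(f"unknown group code {g}")
    # attributed vertices absent from the network (e.g. isolated vertices
    # an edge list cannot represent) have no spokes and are ignored
    members = [v for v in attrs.members(g) if v in net]
    pairs: set[frozenset[str]] = set()
    for a, b in combinations(members, 2):
        if net.has_edge(a, b):
            continue
        if any(True for _ in nx.common_neighbors(net, a, b)):
            pairs.add(frozenset((a, b)))
    return pairs


def wcc(net: nx.Graph, attrs: AttributeMap, g: int) -> dict:
    """Workload closure coefficient of group ``g`` with companions.

    A qualifying (open) pair is *closed* when at least one of its common
    hubs is itself in ``g``; the WCC is the closed fraction.  A group
    with no open pairs is vacuously closed: WCC is reported as 1.0 with
    ``degenerate=True``.  The record also carries the intra-group edge
    density and the mean clustering coefficient of the induced
    subnetwork on ``g``.
    """
    members = [v for v in attrs.members(g) if v in net]
    if not members:
        raise ValueError(f"group {g} has no members in the network")
    in_group = set(members)
    open_pairs = open_pairs_in_group(net, attrs, g)
    closed = sum(
        1
        for pair in open_pairs
        if any(h in in_group for h in nx.common_neighbors(net, *sorted(pair)))
    )
    n_open = len(open_pairs)
    sub = net.subgraph(members)
    n_g = len(members)
    density = sub.number_of_edges() / (n_g * (n_g - 1) / 2) if n_g > 1 else 0.0
    cc = nx.average_clustering(sub) if n_g else 0.0
    return {
        "group": g,
        "label": attrs.group_label(g),
        "n_members": n_g,
        "open_pairs": n_open,
        "closed_pairs": closed,
        "wcc": closed / n_open if n_open else 1.0,
        "degenerate": n_open == 0,
        "density": density,
        "clustering": cc,
    }


def wcc_table(net: nx.Graph, attrs: AttributeMap) -> pd.DataFrame:
    """Per-group WCC table sorted by ascending WCC."""
    attrs.validate(net)
    rows = [wcc(net, attrs, g) for g in range(1, attrs.n_groups + 1)]
    df = pd.DataFrame(rows).sort_values(["wcc", "group"], kind="stable")
    return df.reset_index(drop=True)
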