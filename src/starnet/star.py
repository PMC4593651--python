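"""Star value: per-vertex communication workload and its normalization.

The local subnetwork of a hub vertex is the hub plus its adjacent spokes.
The hub's *workload* is the number of spoke pairs whose shortest
communication path runs through the hub (non-adjacent pairs); the *star
value* (SV) normalizes the workload to ``[0, 1]`` so that a clique hub
scores 0 and a large star hub approaches 1.

Undirected case: with spoke set ``C`` and ``m`` edges among the spokes,

    L  = |C| (|C| - 1) / 2  -  m
    SV = 2 L / |C|**2       =  1 - (2 m + |C|) / |C|**2

Directed case: the neighbourhood is modeled as a tripartite flow with
source-only spokes ``S`` (arc into the hub only), target-only spokes ``T``
(arc from the hub only), and reciprocal spokes ``C``.  Vertices of the
source side ``S + C`` communicate with the target side ``T + C`` through
the hub unless a direct source-to-target arc exists; ``m`` counts those
direct arcs (see :func:`neighborhood_partition` for the weighting of arcs
within ``C``):

    L  = |S| (|T| + |C|)  +  |C| (|T| + (|C| - 1)/2)  -  m
    SV = L / ( |S| (|T| + |C| + 2)/2  +  |T| (|C| + 1)  +  |C|**2 / 2 )

With ``S = T = {}`` the directed formulas reduce exactly to the
undirected ones, so the two measures agree vertexwise on fully reciprocal
digraphs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborhoodPartition",
    "SVRecord",
    "workload_undirected",
    "star_value_undirected",
    "neighborhood_partition",
    "workload_directed",
    "star_value_directed",
    "star_values",
    "sv_table",
    "sv_distribution",
    "moment_stats",
    "summary_stats",
]


@dataclass(frozen=True)
class NeighborhoodPartition:
    """Tripartite decomposition of a hub's directed neighbourhood.

    ``S``: spokes with an arc into the hub only; ``T``: spokes with an
    arc from the hub only; ``C``: reciprocal spokes.  ``m`` is the direct
    source-to-target communication weight and may be half-integral
    because each arc between two reciprocal spokes contributes 1/2 (a
    reciprocal spoke pair thus contributes a full unit, matching the
    single unordered pair it serves).
    """

    hub: str
    S: frozenset[str]
    T: frozenset[str]
    C: frozenset[str]
    m: float

    @property
    def is_empty(self) -> bool:
        return not (self.S or self.T or self.C)


@dataclass(frozen=True)
class SVRecord:
    vertex: str
    n_source_only: int
    n_target_only: int
    n_reciprocal: int
    m: float
    workload: float
    star_value: float | None


def workload_undirected(net: nx.Graph, v: str) -> int:
    """Number of non-adjacent spoke pairs mediated by hub ``v``."""
    if net.is_directed():
        raise ValueError("workload_undirected requires an undirected network")
    spokes = set(net.neighbors(v))
    k = len(spokes)
    if k == 0:
        raise ValueError(f"vertex {v!r} has degree 0: workload undefined")
    m = _edges_within(net, spokes)
    return k * (k - 1) // 2 - m


def _edges_within(net: nx.Graph, vertices: set[str]) -> int:
    """Edge count of the induced subgraph, by scanning adjacency lists."""
    m = 0
    for u in vertices:
        for w in net.neighbors(u):
            if w in vertices:
                m += 1
    return m // 2


def star_value_undirected(net: nx.Graph, v: str) -> float:
    """Normalized workload ``2 L / |C|**2`` in ``[0, 1)``.

    Degree-1 hubs score 0 (no spoke pair to mediate); degree-0 hubs are
    undefined and raise ``ValueError``.
    """
    spokes_n = net.degree(v)
    if spokes_n == 0:
        raise ValueError(f"vertex {v!r} has degree 0: star value undefined")
    L = workload_undirected(net, v)
    return 2.0 * L / spokes_n**2


def neighborhood_partition(net: nx.DiGraph, v: str) -> NeighborhoodPartition:
    """Split the neighbours of ``v`` into source-only / target-only /
    reciprocal sets and count the direct source-to-target arcs ``m``.

    Only arcs from the source side ``S + C`` to the target side ``T + C``
    are counted in ``m`` (arcs ``t -> s`` do not relieve the hub and are
    ignored); an arc between two reciprocal spokes counts 1/2.
    """
    if not net.is_directed():
        raise ValueError("neighborhood_partition requires a directed network")
    preds = set(net.predecessors(v))
    succs = set(net.successors(v))
    C = preds & succs
    S = preds - C
    T = succs - C
    sources = S | C
    targets = T | C
    m = 0.0
    for s in sources:
        for t in net.successors(s):
            if t == v or t not in targets:
                continue
            if s in C and t in C:
                m += 0.5
            else:
                m += 1.0
    return NeighborhoodPartition(v, frozenset(S), frozenset(T), frozenset(C), m)


def workload_directed(p: NeighborhoodPartition) -> float:
    """Mediated source-target pair count, net of direct arcs."""
    nS, nT, nC = len(p.S), len(p.T), len(p.C)
    return nS * (nT + nC) + nC * (nT + (nC - 1) / 2.0) - p.m


def _sv_denominator(p: NeighborhoodPartition, denom: str = "P1") -> float:
    nS, nT, nC = len(p.S), len(p.T), len(p.C)
    if denom == "P1":
        return nS * (nT + nC + 2) / 2.0 + nT * (nC + 1) + nC**2 / 2.0
    if denom == "MAX":
        # workload of the same partition with no direct arcs at all
        return nS * (nT + nC) + nC * (nT + (nC - 1) / 2.0)
    raise ValueError(f"unknown denominator convention {denom!r}")


def star_value_directed(p: NeighborhoodPartition, denom: str = "P1") -> float:
    """Normalized directed workload.

    The default convention ``"P1"`` is the unique reading of the
    normalizer that reduces exactly to the undirected formula when
    ``S = T = {}``; it can marginally exceed 1 for very asymmetric
    neighbourhoods, and such values are reported raw (clipping happens
    only at histogram binning).  ``"MAX"`` normalizes by the workload of
    the arc-free partition instead, guaranteeing ``[0, 1]``.
    """
    if p.is_empty:
        raise ValueError(f"vertex {p.hub!r} has an empty neighbourhood: star value undefined")
    d = _sv_denominator(p, denom)
    if d == 0:
        raise ValueError(f"vertex {p.hub!r}: degenerate zero normalizer")
    return workload_directed(p) / d


def star_values(net: nx.Graph, denom: str = "P1") -> dict[str, float]:
    """Star value for every vertex with a defined value.

    Degree-0 vertices (undirected) and vertices with empty neighbourhoods
    (directed) are omitted; the omission count is logged.
    """
    out: dict[str, float] = {}
    skipped = 0
    for v in sorted(net.nodes):
        try:
            if net.is_directed():
                out[v] = star_value_directed(neighborhood_partition(net, v), denom)
            else:
                out[v] = star_value_undirected(net, v)
        except ValueError:
            skipped += 1
    if skipped:
        logger.info("star_values: %d vertex(es) with undefined SV excluded", skipped)
    return out


def sv_table(net: nx.Graph, denom: str = "P1") -> pd.DataFrame:
    """Per-vertex table: spoke-set sizes, m, workload L, and SV.

    Undirected networks are reported in the reciprocal-only convention
    (``S = T = 0``, ``C`` = adjacency set).
    """
    records: list[SVRecord] = []
    for v in sorted(net.nodes):
        if net.is_directed():
            p = neighborhood_partition(net, v)
            sv = None if p.is_empty else star_value_directed(p, denom)
            L = workload_directed(p) if not p.is_empty else 0.0
            records.append(SVRecord(v, len(p.S), len(p.T), len(p.C), p.m, L, sv))
        else:
            k = net.degree(v)
            if k == 0:
                records.append(SVRecord(v, 0, 0, 0, 0.0, 0.0, None))
                continue
            L = workload_undirected(net, v)
            m = k * (k - 1) / 2.0 - L
            records.append(SVRecord(v, 0, 0, k, m, float(L), 2.0 * L / k**2))
    return pd.DataFrame(
        {
            "vertex": [r.vertex for r in records],
            "n_source_only": [r.n_source_only for r in records],
            "n_target_only": [r.n_target_only for r in records],
            "n_reciprocal": [r.n_reciprocal for r in records],
            "m": [r.m for r in records],
            "workload": [r.workload for r in records],
            "star_value": [r.star_value for r in records],
        }
    )


def sv_distribution(values: Iterable[float] | nx.Graph, bins: int = 20) -> pd.DataFrame:
    """Normalized SV histogram over ``[0, 1]``.

    ``values`` may be a network (SVs are computed first) or a sequence of
    SVs.  Bins are half-open ``[lo, hi)`` with the last closed at 1;
    out-of-range values (possible under the ``"P1"`` directed convention)
    are clipped into the end bins and their count logged.  Counts are
    normalized to sum to 1.
    """
    if isinstance(values, nx.Graph):
        values = list(star_values(values).values())
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no defined star values to bin")
    n_out = int(np.sum((vals < 0) | (vals > 1)))
    if n_out:
        logger.info("sv_distribution: %d value(s) outside [0,1] clipped into end bins", n_out)
    vals = np.clip(vals, 0.0, 1.0)
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "frequency": counts / counts.sum(),
        }
    )


def moment_stats(values: Sequence[float], weights: Sequence[float] | None = None) -> tuple[float, float]:
    """Population skewness and excess kurtosis of a sample.

    skewness = E[((x - mu)/sigma)**3]; kurtosis = E[((x - mu)/sigma)**4] - 3.
    With ``weights`` the moments are weighted (e.g. histogram bin midpoints
    weighted by frequencies).  Requires >=3 values and nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    if weights is None:
        if x.size < 3:
            raise ValueError("need at least 3 values for moment statistics")
        if np.var(x) == 0:
            raise ValueError("zero variance: moments undefined")
        return float(sps.skew(x, bias=True)), float(sps.kurtosis(x, fisher=True, bias=True))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu = float(np.sum(w * x))
    var = float(np.sum(w * (x - mu) ** 2))
    if var == 0:
        raise ValueError("zero variance: moments undefined")
    z = (x - mu) / math.sqrt(var)
    return float(np.sum(w * z**3)), float(np.sum(w * z**4) - 3.0)


def summary_stats(net: nx.Graph, mode: str | None = None, denom: str = "P1") -> dict[str, float]:
    """One summary row: sizes, diameter, characteristic path length,
    mean clustering coefficient, mean star value.

    The statistics are computed on the largest component (``strong`` for
    digraphs, ``connected`` otherwise, unless ``mode`` overrides).  The
    edge count is reported both as unique edges/arcs and as symmetric
    arcs (2x for undirected graphs, matching the convention that counts
    an undirected edge once per direction).  Clustering is computed on
    the undirected view; path lengths respect directionality.
    """
    from .io import largest_component  # local import to avoid cycle

    if mode is None:
        mode = "strong" if net.is_directed() else "connected"
    comp = largest_component(net, mode)
    n = comp.number_of_nodes()
    m_unique = comp.number_of_edges()
    m_sym = m_unique if comp.is_directed() else 2 * m_unique

    total = 0
    count = 0
    diam = 0
    for _, dists in nx.shortest_path_length(comp):
        for target, d in dists.items():
            if d > 0:
                total += d
                count += 1
                if d > diam:
                    diam = d
    cpl = total / count if count else float("nan")

    und = comp if not comp.is_directed() else nx.Graph(comp.edges())
    mean_cc = nx.average_clustering(und) if n else float("nan")
    svs = list(star_values(comp, denom).values())
    mean_sv = float(np.mean(svs)) if svs else float("nan")
    return {
        "n_vertices": n,
        "n_edges_unique": m_unique,
        "n_edges_symmetric": m_sym,
        "diameter": diam,
        "characteristic_path_length": cpl,
        "mean_clustering": mean_cc,
        "mean_star_value": mean_sv,
    }
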