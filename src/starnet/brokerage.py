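"""Gould-Fernandez brokerage census on directed attributed networks.

A vertex ``b`` brokers an ordered pair ``(s, t)`` when the arcs
``s -> b`` and ``b -> t`` exist but the direct arc ``s -> t`` does not
(the reverse arc ``t -> s`` does not disqualify).  Each brokered pair is
classified into one of five roles by the group memberships of the three
vertices, and every broker of a pair receives full credit; all counts
are unnormalized.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd

from .io import AttributeMap

ROLES = ("coordinator", "gatekeeper", "representative", "consultant", "liaison")

__all__ = ["ROLES", "classify_triple", "brokerage_profile", "brokerage_profiles", "brokerage_census"]


def classify_triple(a_s: int, a_b: int, a_t: int) -> str:
    """Role of broker ``b`` for source/broker/target group codes.

    coordinator: all three in one group; gatekeeper: only the source
    differs; representative: only the target differs; consultant: source
    and target share a group the broker is not in; liaison: all three
    groups differ.  The five cases partition all triples.
    """
    if a_s == a_b == a_t:
        return "coordinator"
    if a_b == a_t:  # a_s differs
        return "gatekeeper"
    if a_s == a_b:  # a_t differs
        return "representative"
    if a_s == a_t:  # a_b differs
        return "consultant"
    return "liaison"


def _brokered_pairs(net: nx.DiGraph, b: str) -> Iterable[tuple[str, str]]:
    preds = set(net.predecessors(b))
    for s in preds:
        succ_s = set(net.successors(s))
        for t in net.successors(b):
            if t == s or t == b or s == b:
                continue
            if t in succ_s:
                continue
            yield s, t


def brokerage_profile(net: nx.DiGraph, attrs: AttributeMap, b: str) -> dict[str, int]:
    """Unnormalized count of each of the five roles for vertex ``b``."""
    if not net.is_directed():
        raise ValueError("brokerage is defined on directed networks")
    if b not in net:
        raise ValueError(f"vertex {b!r} not in network")
    counts = dict.fromkeys(ROLES, 0)
    a_b = attrs[b]
    for s, t in _brokered_pairs(net, b):
        counts[classify_triple(attrs[s], a_b, attrs[t])] += 1
    return counts


def brokerage_profiles(net: nx.DiGraph, attrs: AttributeMap) -> pd.DataFrame:
    """Per-vertex role counts plus total brokered-pair count."""
    attrs.validate(net)
    rows = []
    for v in sorted(net.nodes):
        c = brokerage_profile(net, attrs, v)
        rows.append({"vertex": v, "group": attrs[v], **c, "total": sum(c.values())})
    return pd.DataFrame(rows)


def brokerage_census(
    net: nx.DiGraph,
    attrs: AttributeMap,
    k: int = 10,
    orientation: str = "source-target",
) -> dict:
    """Top-``k`` brokers per role and best-broker matrices per group pair.

    Returns ``{"top": {role: DataFrame}, "matrices": {role: DataFrame}}``.
    Top lists rank vertices by role count, ties broken lexicographically.
    Each matrix cell holds the maximum count any single broker achieves
    for that group pair, with ``"-"`` where no qualifying triple exists.

    Matrix orientation (recorded in the DataFrame ``attrs`` metadata):
    under the default ``"source-target"`` convention rows index the
    source group and columns the group the role pairs it with —
    gatekeeper and representative use the broker-side group implied by
    the role definition, consultant uses (spoke group, broker group),
    liaison uses (source group, target group).
    """
    attrs.validate(net)
    K = attrs.n_groups
    # per-role, per-(group pair), per-broker counts
    cell_counts: dict[str, dict[tuple[int, int], dict[str, int]]] = {r: {} for r in ROLES}
    totals: dict[str, dict[str, int]] = {r: {} for r in ROLES}
    for b in sorted(net.nodes):
        a_b = attrs[b]
        for s, t in _brokered_pairs(net, b):
            a_s, a_t = attrs[s], attrs[t]
            role = classify_triple(a_s, a_b, a_t)
            totals[role][b] = totals[role].get(b, 0) + 1
            if role == "coordinator":
                key = (a_s, a_s)
            elif role == "gatekeeper":
                key = (a_s, a_b)  # outside source into the broker/target group
            elif role == "representative":
                key = (a_s, a_t)  # broker's own group toward the outside target
            elif role == "consultant":
                key = (a_s, a_b)  # spoke group served by an outside broker
            else:  # liaison
                key = (a_s, a_t)
            cell = cell_counts[role].setdefault(key, {})
            cell[b] = cell.get(b, 0) + 1

    labels = [attrs.group_label(g) for g in range(1, K + 1)]
    top: dict[str, pd.DataFrame] = {}
    matrices: dict[str, pd.DataFrame] = {}
    for role in ROLES:
        ranked = sorted(totals[role].items(), key=lambda it: (-it[1], it[0]))[:k]
        top[role] = pd.DataFrame(ranked, columns=["vertex", "count"])
        mat = pd.DataFrame("-", index=labels, columns=labels, dtype=object)
        for (g, h), per_broker in cell_counts[role].items():
            # best broker shown as "vertex:count"; ties to the smallest vertex
            best = max(sorted(per_broker.items()), key=lambda it: it[1])
            mat.iloc[g - 1, h - 1] = f"{best[0]}:{best[1]}"
        mat.attrs["orientation"] = orientation
        matrices[role] = mat
    return {"top": top, "matrices": matrices}
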