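"""Independent brute-force oracles used to cross-check the implementation.

Every function here recomputes a quantity by direct enumeration of the
defining objects (pairs, triples) rather than via the closed-form or
incremental routes the package uses.  Intended for graphs of at most a
dozen vertices.
"""

from itertools import combinations

import networkx as nx


def workload_undirected_bf(net: nx.Graph, v: str) -> int:
    """Count non-adjacent neighbour pairs of ``v`` one pair at a time."""
    nbrs = sorted(net.neighbors(v))
    return sum(1 for a, b in combinations(nbrs, 2) if not net.has_edge(a, b))


def workload_directed_bf(net: nx.DiGraph, v: str) -> float:
    """Enumerate mediated source-target pairs of hub ``v`` directly.

    Sources are in-neighbours, targets out-neighbours; a reciprocal
    neighbour is both.  Each source/target combination contributes its
    full mediation demand minus the direct relief: 1 if the direct
    source->target arc exists (0.5 per arc for a reciprocal pair, which
    is a single unordered communication pair with two possible arcs).
    """
    preds = set(net.predecessors(v))
    succs = set(net.successors(v))
    C = preds & succs
    S = preds - C
    T = succs - C
    total = 0.0
    for x in S:
        for y in (T | C) - {x}:
            total += 1.0 - (1.0 if net.has_edge(x, y) else 0.0)
    for x in C:
        for y in T:
            total += 1.0 - (1.0 if net.has_edge(x, y) else 0.0)
    for x, y in combinations(sorted(C), 2):
        relief = 0.5 * net.has_edge(x, y) + 0.5 * net.has_edge(y, x)
        total += 1.0 - relief
    return total


def wcc_bf(net: nx.Graph, codes: dict[str, int], g: int) -> tuple[int, int]:
    """(open, closed) same-group spoke-pair counts by triple enumeration."""
    members = sorted(v for v, c in codes.items() if c == g)
    n_open = n_closed = 0
    for a, b in combinations(members, 2):
        if net.has_edge(a, b):
            continue
        hubs = [h for h in net.nodes if h not in (a, b) and net.has_edge(h, a) and net.has_edge(h, b)]
        if hubs:
            n_open += 1
            if any(codes[h] == g for h in hubs):
                n_closed += 1
    return n_open, n_closed


def brokerage_bf(net: nx.DiGraph, codes: dict[str, int], b: str) -> dict[str, int]:
    """Five role counts for broker ``b`` by full ordered-triple scan."""
    counts = {"coordinator": 0, "gatekeeper": 0, "representative": 0, "consultant": 0, "liaison": 0}
    for s in net.nodes:
        for t in net.nodes:
            if len({s, b, t}) != 3:
                continue
            if not (net.has_edge(s, b) and net.has_edge(b, t)):
                continue
            if net.has_edge(s, t):
                continue
            a_s, a_b, a_t = codes[s], codes[b], codes[t]
            if a_s == a_b == a_t:
                counts["coordinator"] += 1
            elif a_s != a_b and a_b == a_t:
                counts["gatekeeper"] += 1
            elif a_s == a_b and a_t != a_b:
                counts["representative"] += 1
            elif a_s == a_t and a_b != a_s:
                counts["consultant"] += 1
            else:
                counts["liaison"] += 1
    return counts


def mean_sv_er_closed_form(n: int, p: float) -> float:
    """Asymptotic mean star value of G(n, p): 1 - p + (p - 1)/(n p)."""
    return 1.0 - p + (p - 1.0) / (n * p)
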