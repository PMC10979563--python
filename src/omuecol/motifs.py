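"""Trio-motif census anchored on the most abundant OMU, and PN ratios.

Trios (connected 3-node subgraphs of the signed co-occurrence network)
are the smallest network modules.  The census distinguishes them by
topology (chain vs triangle), by the role of the most abundant OMU
(MAO) — a trio member, either central or terminal, or an outside
"handle" neighbour — and by the multiset of edge signs.  The default
catalog enumerates every distinguishable signed configuration:

* triangle with MAO as member: 2 MAO-incident signs (unordered) x
  opposite-edge sign = 6 classes;
* chain with MAO central: unordered pair of incident signs = 3 classes;
* chain with MAO terminal: (incident sign, far sign) ordered = 4 classes;

13 member-mode classes in all, plus handle-mode classes keyed by
topology x sign multiset.  Anything outside the catalog lands in an
explicit ``unclassified`` bucket.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .omu_table import OmuTable


@dataclass
class TrioCensus:
    mao_id: str
    mode: str                      # "member" or "handle"
    counts: dict[str, int]
    total: int


@dataclass
class PnRatio:
    n_positive: int
    n_negative: int

    @property
    def ratio(self) -> float:
        if self.n_negative == 0:
            return math.inf
        return self.n_positive / self.n_negative


def find_mao(table: OmuTable) -> str:
    """Most abundant OMU: maximal total abundance (occurrence count for
    presence/absence tables); ties broken lexicographically."""
    totals = table.counts.sum(axis=1)
    if totals.sum() == 0:
        raise ValueError("all-zero table has no most abundant OMU")
    best = totals.max()
    return sorted(totals.index[totals == best])[0]


def default_catalog() -> list[str]:
    """All member-mode class keys of the shipped catalog."""
    keys = []
    for inc in ("++", "+-", "--"):
        for opp in ("+", "-"):
            keys.append(f"triangle|mao-member|inc:{inc}|opp:{opp}")
    for pair in ("++", "+-", "--"):
        keys.append(f"chain|mao-central|{pair}")
    for near in ("+", "-"):
        for far in ("+", "-"):
            keys.append(f"chain|mao-end|near:{near}|far:{far}")
    return keys


def _sorted_signs(*signs: str) -> str:
    return "".join(sorted(signs))  # ASCII: '+' sorts before '-'


def classify_trio(net: nx.Graph, trio: tuple, mao: str) -> str:
    """Canonical class key of one connected trio."""
    a, b, c = trio
    edges = [
        (u, v) for u, v in combinations(trio, 2) if net.has_edge(u, v)
    ]
    sign = {frozenset(e): net.edges[e].get("sign", "+") for e in edges}
    if len(edges) == 3:
        topo = "triangle"
    elif len(edges) == 2:
        topo = "chain"
    else:
        return "unclassified"
    if mao in trio:
        others = [n for n in trio if n != mao]
        if topo == "triangle":
            inc = _sorted_signs(
                sign[frozenset((mao, others[0]))], sign[frozenset((mao, others[1]))]
            )
            opp = sign[frozenset(others)]
            return f"triangle|mao-member|inc:{inc}|opp:{opp}"
        deg = {n: 0 for n in trio}
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        if deg[mao] == 2:
            pair = _sorted_signs(*(sign[frozenset(e)] for e in edges))
            return f"chain|mao-central|{pair}"
        center = next(n for n in trio if deg[n] == 2)
        near = sign[frozenset((mao, center))]
        far_node = next(n for n in others if n != center)
        far = sign[frozenset((center, far_node))]
        return f"chain|mao-end|near:{near}|far:{far}"
    # handle mode: MAO outside the trio
    if topo == "triangle":
        signs = _sorted_signs(*(sign[frozenset(e)] for e in edges))
        return f"triangle|handle|{signs}"
    pair = _sorted_signs(*(sign[frozenset(e)] for e in edges))
    return f"chain|handle|{pair}"


def trio_census(
    net: nx.Graph, mao_id: str, mode: str = "member",
    catalog: list[str] | None = None,
) -> TrioCensus:
    """Census of connected trios.

    ``member`` mode counts connected 3-node subgraphs containing the MAO;
    ``handle`` mode counts connected trios *not* containing the MAO in
    which at least one trio node is adjacent to the MAO (the MAO hangs
    off the trio by a separate handle link).
    """
    if mao_id not in net:
        raise ValueError(f"MAO {mao_id!r} not in network")
    if mode not in {"member", "handle"}:
        raise ValueError(f"unknown mode {mode!r}")
    if catalog is None:
        catalog = default_catalog() + [
            f"triangle|handle|{s}" for s in ("+++", "++-", "+--", "---")
        ] + [f"chain|handle|{s}" for s in ("++", "+-", "--")]
    counts: dict[str, int] = {}
    total = 0
    nodes = sorted(net.nodes)
    for trio in combinations(nodes, 3):
        sub_edges = sum(
            1 for u, v in combinations(trio, 2) if net.has_edge(u, v)
        )
        if sub_edges < 2:
            continue
        if sub_edges == 2:  # chain: connected iff exactly one node has deg 2
            deg = {n: 0 for n in trio}
            for u, v in combinations(trio, 2):
                if net.has_edge(u, v):
                    deg[u] += 1
                    deg[v] += 1
            if max(deg.values()) != 2:
                continue
        if mode == "member":
            if mao_id not in trio:
                continue
        else:
            if mao_id in trio:
                continue
            if not any(net.has_edge(mao_id, n) for n in trio):
                continue
        key = classify_trio(net, trio, mao_id)
        if key not in catalog:
            key = "unclassified"
        counts[key] = counts.get(key, 0) + 1
        total += 1
    return TrioCensus(mao_id=mao_id, mode=mode, counts=counts, total=total)


def pn_ratio(net: nx.Graph, edges=None) -> PnRatio:
    """Positive-to-negative link ratio of a graph (or an edge subset)."""
    if edges is None:
        edges = list(net.edges)
    if not edges:
        raise ValueError("no edges")
    pos = sum(1 for e in edges if net.edges[e].get("sign", "+") == "+")
    return PnRatio(n_positive=pos, n_negative=len(edges) - pos)
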