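"""Domain co-occurrence networks.

Nodes are domain families (with the total number of observed instances as
an attribute); an edge between two families is weighted by the number of
proteins in which both occur — counted once per protein, however many
instance pairs the protein contains.  A self-edge on family f counts
proteins carrying at least two copies of f (multi-GHx proteins).

The association-map filter used in practice keeps only pairs observed in
more than one protein (``filter_min_weight(net, 2)``).
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd

from .architecture import ProteinArchitecture


def build_network(architectures: list[ProteinArchitecture]) -> nx.Graph:
    """Count family co-occurrence across overlap-resolved architectures."""
    g = nx.Graph()
    for arch in architectures:
        fams = arch.families
        counts: dict[str, int] = {}
        for f in fams:
            counts[f] = counts.get(f, 0) + 1
        for f, c in counts.items():
            if f not in g:
                g.add_node(f, total_count=0)
            g.nodes[f]["total_count"] += c
        distinct = sorted(counts)
        for a, b in combinations(distinct, 2):
            w = g.edges[a, b]["weight"] if g.has_edge(a, b) else 0
            g.add_edge(a, b, weight=w + 1)
        for f, c in counts.items():
            if c >= 2:
                w = g.edges[f, f]["weight"] if g.has_edge(f, f) else 0
                g.add_edge(f, f, weight=w + 1)
    return g


def filter_min_weight(
    net: nx.Graph, min_weight: int, keep_singletons: bool = False
) -> nx.Graph:
    """Drop edges below ``min_weight``; idempotent.

    Nodes left with no incident edge are dropped, unless
    ``keep_singletons`` is set and the node has a nonzero total_count.
    """
    g = net.copy()
    drop = [
        (a, b) for a, b, w in g.edges(data="weight") if w < min_weight
    ]
    g.remove_edges_from(drop)
    isolated = [
        n
        for n in g.nodes
        if g.degree(n) == 0
        and not (keep_singletons and g.nodes[n].get("total_count", 0) > 0)
    ]
    g.remove_nodes_from(isolated)
    return g


def connected_clusters(net: nx.Graph) -> list[set[str]]:
    """Connected components, largest first (ties: lexicographic)."""
    comps = [set(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), sorted(c)))
    return comps


def total_edge_weight(net: nx.Graph) -> int:
    return sum(w for _a, _b, w in net.edges(data="weight"))


def write_edge_list(net: nx.Graph, path) -> None:
    """Edge list CSV (family_a, family_b, weight); self-edges included."""
    rows = sorted(
        (min(a, b), max(a, b), w) for a, b, w in net.edges(data="weight")
    )
    pd.DataFrame(rows, columns=["family_a", "family_b", "weight"]).to_csv(
        path, index=False
    )


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
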