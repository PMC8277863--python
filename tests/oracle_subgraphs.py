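"""Independent brute-force subgraph-counting oracle built on NetworkX.

Enumerates every edge subset with itertools, keeps the connected ones,
and groups them by pairwise isomorphism checks (networkx VF2 with
element and bond-order matching).  Shares no code with the package's
enumeration path, so agreement is a real cross-check.
"""

import itertools

import networkx as nx

from graphbac.molgraph import MasterGraph, total_hydrogens


def to_nx(elements, edges) -> nx.Graph:
    G = nx.Graph()
    for v, el in enumerate(elements):
        G.add_node(v, element=el)
    for i, j, o in edges:
        G.add_edge(i, j, order=o)
    return G


def _node_match(a, b):
    return a["element"] == b["element"]


def _edge_match(a, b):
    return a["order"] == b["order"]


def isomorphic(G, H) -> bool:
    return nx.is_isomorphic(G, H, node_match=_node_match, edge_match=_edge_match)


def brute_force_counts(g: MasterGraph, max_edges: int):
    """List of (representative nx.Graph, n_edges, count) isomorphism classes.

    Zeroth-order classes are single labeled nodes; the lumped-hydrogen
    descriptor is returned separately as ("H", count).
    """
    classes: list[tuple[nx.Graph, int, int]] = []
    for el in sorted(set(g.elements)):
        rep = nx.Graph()
        rep.add_node(0, element=el)
        classes.append((rep, 0, g.elements.count(el)))
    G = to_nx(g.elements, g.edges)
    for k in range(1, max_edges + 1):
        for subset in itertools.combinations(range(len(g.edges)), k):
            picked = [g.edges[e] for e in subset]
            H = G.edge_subgraph([(i, j) for i, j, _ in picked])
            if not nx.is_connected(H):
                continue
            for idx, (rep, n_e, count) in enumerate(classes):
                if n_e == k and isomorphic(H, rep):
                    classes[idx] = (rep, n_e, count + 1)
                    break
            else:
                classes.append((nx.Graph(H), k, 1))
    return classes, total_hydrogens(g)


def key_to_nx(key: str) -> nx.Graph:
    """Decode a canonical key back into a labeled NetworkX graph."""
    labels_part, adj_part = key.split("|")
    labels = labels_part.split(",")
    G = nx.Graph()
    for v, el in enumerate(labels):
        G.add_node(v, element=el)
    pos = 0
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            order = int(adj_part[pos])
            pos += 1
            if order:
                G.add_edge(a, b, order=order)
    return G


def assert_counts_match(g: MasterGraph, counts, max_edges: int):
    """Pattern-for-pattern, count-for-count agreement with the oracle."""
    classes, n_h = brute_force_counts(g, max_edges)
    mine = {p: c for p, c in counts.items() if p.key != "H"}
    h_count = next((c for p, c in counts.items() if p.key == "H"), 0)
    assert h_count == (n_h if n_h else 0), g.id
    assert len(mine) == len(classes), (
        f"{g.id}: {len(mine)} patterns vs oracle {len(classes)} classes"
    )
    for pattern, count in mine.items():
        decoded = key_to_nx(pattern.key)
        matches = [
            c for rep, n_e, c in classes
            if n_e == pattern.n_edges and isomorphic(decoded, rep)
        ]
        assert matches == [count], (
            f"{g.id}: pattern {pattern.label} count {count} vs oracle {matches}"
        )
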