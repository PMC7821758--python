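"""Naive enumeration reference implementations for cross-checking.

Everything here trades efficiency for transparency: distances come from
Floyd-Warshall on the dense adjacency matrix, betweenness and stress from
explicit enumeration of every shortest path, EPC from iterating all 2^m
edge subsets, BottleNeck from walking parent chains node by node, AUC from
counting pairs, and the best-modularity partition from enumerating every
set partition of the nodes.  These routines are deliberately kept on
separate code paths from the production implementations they check; they
are only usable on small graphs.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["reference_centralities", "exact_epc", "brute_force_auc",
           "exhaustive_best_partition", "set_partitions"]

_DMNC_EPS = 1.7


def _floyd_warshall(G: nx.Graph, nodes: list) -> np.ndarray:
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in G.edges:
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d


def reference_centralities(G: nx.Graph) -> pd.DataFrame:
    """All eight deterministic scores by direct enumeration."""
    nodes = sorted(G.nodes)
    d = _floyd_warshall(G, nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    rows = {}

    # shortest-path enumeration for betweenness / stress
    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for s, t in combinations(nodes, 2):
        if np.isinf(d[idx[s], idx[t]]):
            continue
        paths = list(nx.all_shortest_paths(G, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            on = sum(1 for p in paths if v in p)
            stress[v] += on
            betweenness[v] += on / len(paths)

    bottleneck = _reference_bottleneck(G, nodes)

    for v in nodes:
        neigh = sorted(G.neighbors(v))
        deg = len(neigh)
        mnc, dmnc = 0, 0.0
        if neigh:
            sub = G.subgraph(neigh)
            comp = max(nx.connected_components(sub), key=len)
            mnc = len(comp)
            if mnc > 1:
                e = sum(1 for a, b in combinations(sorted(comp), 2)
                        if G.has_edge(a, b))
                dmnc = e / mnc**_DMNC_EPS
        dv = d[idx[v]]
        finite = np.isfinite(dv) & (dv > 0)
        closeness = float((1.0 / dv[finite]).sum())
        comp_mask = np.isfinite(dv)
        n_c = int(comp_mask.sum())
        if n_c > 1:
            sub_d = d[np.ix_(comp_mask, comp_mask)]
            diam = float(sub_d.max())
            radial = float((diam + 1 - dv[finite]).sum() / (n_c - 1))
        else:
            radial = 0.0
        rows[v] = (dmnc, mnc, deg, bottleneck[v], closeness, radial,
                   betweenness[v], stress[v])
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["DMNC", "MNC", "Degree", "BottleNeck", "Closeness",
                 "Radiality", "Betweenness", "Stress"]).sort_index()


def _reference_bottleneck(G: nx.Graph, nodes: list) -> dict:
    """BottleNeck by explicit parent-chain walking per tree node."""
    score = {v: 0 for v in nodes}
    for s in nodes:
        parent = {s: None}
        frontier = [s]
        seen = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(G.neighbors(u)):
                    if w not in parent:
                        parent[w] = u
                        seen.append(w)
                        nxt.append(w)
            frontier = nxt
        n_s = len(seen)
        for v in seen:
            if v == s:
                continue
            load = 0
            for w in seen:  # does w's root-path pass through v?
                x = w
                while x is not None:
                    if x == v:
                        load += 1
                        break
                    x = parent[x]
            if load > n_s / 4.0:
                score[v] += 1
    return score


def exact_epc(G: nx.Graph, retain_p: float = 0.5):
    """Exact EPC expectation and variance by enumerating edge subsets."""
    nodes = sorted(G.nodes)
    edges = list(G.edges)
    m = len(edges)
    mean = pd.Series(0.0, index=nodes)
    second = pd.Series(0.0, index=nodes)
    for mask in range(2**m):
        kept = [edges[i] for i in range(m) if mask >> i & 1]
        weight = retain_p**len(kept) * (1 - retain_p)**(m - len(kept))
        H = nx.Graph()
        H.add_nodes_from(nodes)
        H.add_edges_from(kept)
        for comp in nx.connected_components(H):
            for v in comp:
                x = len(comp) - 1
                mean[v] += weight * x
                second[v] += weight * x * x
    return mean, second - mean**2


def brute_force_auc(pos, neg) -> float:
    """AUC by pair counting: wins plus half-ties over all pairs."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


def set_partitions(items: list):
    """Yield every set partition (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_partition(G: nx.Graph):
    """Globally modularity-optimal partition by full enumeration.

    Returns (assignment dict, Q).  Feasible only for graphs with at most
    ~10 nodes (Bell numbers grow super-exponentially).
    """
    m = G.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    nodes = sorted(G.nodes)
    deg = dict(G.degree)
    best_q, best_assign = -np.inf, None
    for part in set_partitions(nodes):
        q = 0.0
        for block in part:
            bs = set(block)
            m_c = sum(1 for a, b in combinations(sorted(bs), 2)
                      if G.has_edge(a, b))
            d_c = sum(deg[v] for v in bs)
            q += m_c / m - (d_c / (2.0 * m)) ** 2
        if q > best_q + 1e-12:
            best_q = q
            best_assign = {v: i for i, block in enumerate(part)
                           for v in block}
    return best_assign, best_q
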