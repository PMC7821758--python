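"""Nine node-topology scores on a PPI graph and top-k hub-gene calling.

The score battery mirrors the cytoHubba plugin: Degree, MNC (size of the
largest connected component of the neighbourhood-induced subgraph), DMNC
(edges of that component divided by its node count to the power 1.7), EPC
(edge-percolated component: mean number of nodes still reachable across
random edge-retention replicates), BottleNeck (number of shortest-path-tree
roots for which the node carries more than a quarter of the tree), harmonic
Closeness (sum of inverse distances), Radiality, Betweenness (unordered
source-target pairs) and Stress (raw geodesic counts).

Hub genes are the union, over all nine columns, of the genes holding the k
highest scores per column (ties with the k-th value included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["build_ppi", "neighborhood_scores", "epc_score",
           "bottleneck_score", "distance_scores", "path_count_scores",
           "score_table", "merge_top_k", "HubSet", "ALGORITHM_ORDER"]

#: column order of the score table (published-table convention)
ALGORITHM_ORDER = ("DMNC", "MNC", "Degree", "EPC", "BottleNeck",
                   "Closeness", "Radiality", "Betweenness", "Stress")

DMNC_EPSILON = 1.7  # exponent of the DMNC density normalisation


def build_ppi(edges: pd.DataFrame, min_score: float = 0.400) -> nx.Graph:
    """Simple undirected graph from a scored (STRING-style) edge list.

    ``edges`` needs columns protein1, protein2, combined_score; the score
    scale (0-1000 vs 0-1) is auto-detected and 0-1000 inputs are divided
    by 1000.  Duplicate pairs collapse keeping the maximum score;
    self-loops are dropped; edges below ``min_score`` (inclusive keep at
    the boundary) are filtered out.
    """
    if edges.empty:
        warnings.warn("empty PPI edge list")
        return nx.Graph()
    score = edges["combined_score"].astype(float)
    if score.max() > 1.0:
        score = score / 1000.0
    G = nx.Graph()
    for (a, b), s in zip(zip(edges["protein1"], edges["protein2"]), score):
        if a == b:
            continue
        if G.has_edge(a, b):
            G[a][b]["score"] = max(G[a][b]["score"], s)
        else:
            G.add_edge(a, b, score=s)
    drop = [(a, b) for a, b, d in G.edges(data=True) if d["score"] < min_score]
    G.remove_edges_from(drop)
    G.remove_nodes_from(list(nx.isolates(G)))
    if G.number_of_edges() == 0:
        warnings.warn("all PPI edges fell below the confidence threshold")
    return G


def neighborhood_scores(G: nx.Graph) -> pd.DataFrame:
    """Degree, MNC and DMNC per node.

    MNC(v) is the node count of the largest connected component of the
    subgraph induced by N(v) (0 for an isolated node); DMNC(v) is that
    component's edge count divided by its node count to the power 1.7
    (0 when the component has <= 1 node).
    """
    rows = {}
    for v in G.nodes:
        neigh = list(G.neighbors(v))
        deg = len(neigh)
        if not neigh:
            rows[v] = (0.0, 0, 0)
            continue
        sub = G.subgraph(neigh)
        comp = max(nx.connected_components(sub), key=len)
        mnc = len(comp)
        if mnc <= 1:
            dmnc = 0.0
        else:
            e = sub.subgraph(comp).number_of_edges()
            dmnc = e / mnc**DMNC_EPSILON
        rows[v] = (dmnc, mnc, deg)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["DMNC", "MNC", "Degree"])


def epc_score(G: nx.Graph, replicates: int = 1000, retain_p: float = 0.5,
              seed: int = 0) -> pd.Series:
    """Edge-percolated component score, Monte-Carlo estimated.

    Each replicate retains every edge independently with probability
    ``retain_p``; a node's replicate value is the number of other nodes it
    remains connected to, and EPC is the mean over replicates.
    """
    nodes = sorted(G.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return pd.Series(dtype=float, name="EPC")
    edges = np.array([(index[u], index[v]) for u, v in G.edges], dtype=int)
    rng = np.random.default_rng(seed)
    total = np.zeros(n)
    for _ in range(replicates):
        if len(edges):
            keep = edges[rng.random(len(edges)) < retain_p]
        else:
            keep = edges
        if len(keep):
            A = coo_matrix((np.ones(len(keep)), (keep[:, 0], keep[:, 1])),
                           shape=(n, n))
            _, labels = connected_components(A, directed=False)
            sizes = np.bincount(labels)
            total += sizes[labels] - 1
    return pd.Series(total / replicates, index=nodes, name="EPC")


def _bfs_tree(adj: dict, root):
    """BFS tree with parent = earliest-discovered neighbour.

    Neighbours are explored in ascending node-id order so discovery is
    deterministic.  Returns (visit order, parent map).
    """
    parent = {root: None}
    visit = [root]
    queue = [root]
    while queue:
        u = queue.pop(0)
        for w in adj[u]:
            if w not in parent:
                parent[w] = u
                visit.append(w)
                queue.append(w)
    return visit, parent


def bottleneck_score(G: nx.Graph) -> pd.Series:
    """BottleNeck score: trees in which a node is a quarter-load cut point.

    For every root s a breadth-first shortest-path tree is grown
    (deterministic parent rule: earliest-discovered neighbour, ascending
    node-id exploration).  A node v != s scores one point for s when the
    number of tree nodes whose root-path passes through v (v included,
    i.e. v's subtree size) strictly exceeds n_s / 4, with n_s the nodes
    reachable from s.
    """
    nodes = sorted(G.nodes)
    order = {v: i for i, v in enumerate(nodes)}
    adj = {v: sorted(G.neighbors(v), key=order.__getitem__) for v in nodes}
    score = {v: 0 for v in nodes}
    for s in nodes:
        visit, parent = _bfs_tree(adj, s)
        n_s = len(visit)
        subtree = {v: 1 for v in visit}
        for v in reversed(visit):
            if parent[v] is not None:
                subtree[parent[v]] += subtree[v]
        for v in visit:
            if v != s and subtree[v] > n_s / 4.0:
                score[v] += 1
    return pd.Series(score, name="BottleNeck")


def distance_scores(G: nx.Graph) -> pd.DataFrame:
    """Harmonic Closeness and Radiality per node.

    Closeness(v) = sum of 1/d(v, u) over reachable u (others contribute 0);
    Radiality(v) = sum over v's component of (diameter + 1 - d(v, u)) /
    (component size - 1).  Singleton components score 0.
    """
    closeness = nx.harmonic_centrality(G)
    radiality = {v: 0.0 for v in G.nodes}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        n_c = len(comp)
        if n_c < 2:
            continue
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dist.values())
        for v in comp:
            radiality[v] = sum(diam + 1 - d for u, d in dist[v].items()
                               if u != v) / (n_c - 1)
    return pd.DataFrame({"Closeness": pd.Series(closeness),
                         "Radiality": pd.Series(radiality)})


def _geodesic_matrices(G: nx.Graph):
    """All-pairs distances and shortest-path counts by per-source BFS."""
    nodes = sorted(G.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = index[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        queue = [s]
        while queue:
            u = queue.pop(0)
            ui = index[u]
            for w in G.neighbors(u):
                wi = index[w]
                if np.isinf(dist[si, wi]):
                    dist[si, wi] = dist[si, ui] + 1
                    queue.append(w)
                if dist[si, wi] == dist[si, ui] + 1:
                    sigma[si, wi] += sigma[si, ui]
    return nodes, dist, sigma


def path_count_scores(G: nx.Graph) -> pd.DataFrame:
    """Betweenness and Stress per node over unordered source-target pairs.

    Betweenness(v) sums the geodesic fraction sigma_st(v)/sigma_st; Stress
    sums the raw geodesic count sigma_st(v), both over pairs s != v != t.
    """
    bet = {v: float(b) for v, b in
           nx.betweenness_centrality(G, normalized=False).items()}
    nodes, dist, sigma = _geodesic_matrices(G)
    n = len(nodes)
    stress = {}
    for vi, v in enumerate(nodes):
        through = np.outer(sigma[:, vi], sigma[vi, :])
        on_path = (dist[:, vi][:, None] + dist[vi, :][None, :]) == dist
        with np.errstate(invalid="ignore"):
            counts = np.where(on_path & np.isfinite(dist), through, 0.0)
        counts[vi, :] = 0.0
        counts[:, vi] = 0.0
        np.fill_diagonal(counts, 0.0)
        stress[v] = float(counts.sum() / 2.0)
    return pd.DataFrame({"Betweenness": pd.Series(bet),
                         "Stress": pd.Series(stress)})


def score_table(G: nx.Graph, *, epc_replicates: int = 1000,
                epc_retain_p: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """All nine topology scores, columns in the published-table order."""
    if G.number_of_nodes() == 0:
        return pd.DataFrame(columns=list(ALGORITHM_ORDER))
    parts = [neighborhood_scores(G),
             epc_score(G, epc_replicates, epc_retain_p, seed),
             bottleneck_score(G),
             distance_scores(G),
             path_count_scores(G)]
    table = pd.concat(parts, axis=1)
    return table[list(ALGORITHM_ORDER)].sort_index()


@dataclass
class HubSet:
    """Hub genes with, per gene, the algorithms that ranked it top-k."""

    provenance: dict  # gene -> sorted list of algorithm names

    @property
    def genes(self) -> set:
        return set(self.provenance)

    def __contains__(self, gene) -> bool:
        return gene in self.provenance

    def as_frame(self) -> pd.DataFrame:
        rows = [(g, ",".join(algs)) for g, algs in
                sorted(self.provenance.items())]
        return pd.DataFrame(rows, columns=["gene", "algorithms"])


def merge_top_k(scores: pd.DataFrame, k: int = 5) -> HubSet:
    """Union of per-column top-k genes, ties at rank k included."""
    if scores.shape[1] == 0:
        raise ValueError("score table has no algorithm columns")
    provenance: dict = {}
    for col in scores.columns:
        s = scores[col].dropna()
        if len(s) <= k:
            selected = s.index
        else:
            kth = s.nlargest(k).iloc[-1]
            selected = s.index[s >= kth]
        for g in selected:
            provenance.setdefault(g, []).append(col)
    return HubSet({g: sorted(a) for g, a in provenance.items()})
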