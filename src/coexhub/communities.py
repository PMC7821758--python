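"""Module detection on the GCN: three algorithms, modularity selection.

Three community-detection algorithms are run on the co-expression network
— multi-level (Louvain) greedy modularity optimisation, asynchronous label
propagation, and Girvan–Newman edge-betweenness removal — and the partition
with the highest Newman modularity

    Q = sum_c [ m_c / m  -  (d_c / 2m)^2 ]

(m total edges, m_c within-module edges, d_c total degree of module c) is
kept.  Modules below a minimum size are marked unassigned and the survivors
renumbered m1, m2, ... by descending size.

Multi-level and edge-betweenness run on igraph's C implementations; label
propagation is implemented here with seeded visit order and seeded uniform
tie-breaking.
"""

from __future__ import annotations

import random
import warnings

import igraph as ig
import networkx as nx
import numpy as np

from .containers import UNASSIGNED, Partition

__all__ = ["modularity", "detect_multilevel", "detect_label_propagation",
           "detect_edge_betweenness", "select_partition"]

#: fixed preference order used to break exact modularity ties
_ALGORITHM_PREFERENCE = ("multilevel", "label_propagation", "edge_betweenness")


def modularity(G: nx.Graph, assignment) -> float:
    """Newman modularity Q of a node->module assignment on G."""
    m = G.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    within: dict = {}
    degree: dict = {}
    for v in G.nodes:
        degree[assignment[v]] = degree.get(assignment[v], 0) + G.degree(v)
    for u, v in G.edges:
        if assignment[u] == assignment[v]:
            within[assignment[u]] = within.get(assignment[u], 0) + 1
    q = 0.0
    for c, d_c in degree.items():
        q += within.get(c, 0) / m - (d_c / (2.0 * m)) ** 2
    return q


def _to_igraph(G: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = sorted(G.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(n=len(nodes),
                 edges=[(index[u], index[v]) for u, v in G.edges])
    return g, nodes


def _partition_from_membership(G, nodes, membership, algorithm) -> Partition:
    assignment = {v: int(c) for v, c in zip(nodes, membership)}
    return Partition(assignment, algorithm, modularity(G, assignment))


def detect_multilevel(G: nx.Graph, seed: int = 0,
                      resolution: float = 1.0) -> Partition:
    """Greedy two-phase (Louvain) modularity optimisation."""
    if G.number_of_nodes() == 0:
        return Partition({}, "multilevel", float("nan"))
    g, nodes = _to_igraph(G)
    ig.set_random_number_generator(random.Random(int(seed)))
    clusters = g.community_multilevel(resolution=resolution)
    return _partition_from_membership(G, nodes, clusters.membership, "multilevel")


def detect_label_propagation(G: nx.Graph, seed: int = 0,
                             max_sweeps: int = 100) -> Partition:
    """Asynchronous label propagation with seeded order and tie-breaks.

    Each sweep visits nodes in a fresh seeded random order; a node adopts
    the most frequent label among its neighbours, ties broken uniformly at
    random from the tied set (keeping the current label when it is among
    the tied leaders).  Stops when a full sweep changes nothing, or after
    ``max_sweeps`` sweeps with a warning.
    """
    nodes = sorted(G.nodes)
    if not nodes:
        return Partition({}, "label_propagation", float("nan"))
    rng = np.random.default_rng(seed)
    labels = {v: i for i, v in enumerate(nodes)}
    for _ in range(max_sweeps):
        changed = False
        for vi in rng.permutation(len(nodes)):
            v = nodes[vi]
            neigh = list(G.neighbors(v))
            if not neigh:
                continue
            counts: dict = {}
            for u in neigh:
                counts[labels[u]] = counts.get(labels[u], 0) + 1
            best = max(counts.values())
            tied = sorted(lab for lab, c in counts.items() if c == best)
            if labels[v] in tied:
                continue
            labels[v] = tied[int(rng.integers(len(tied)))]
            changed = True
        if not changed:
            break
    else:
        warnings.warn("label propagation stopped at max_sweeps without converging")
    # canonical relabel in node order
    remap: dict = {}
    for v in nodes:
        remap.setdefault(labels[v], len(remap))
    assignment = {v: remap[labels[v]] for v in nodes}
    q = modularity(G, assignment) if G.number_of_edges() else float("nan")
    return Partition(assignment, "label_propagation", q)


def detect_edge_betweenness(G: nx.Graph) -> Partition:
    """Girvan–Newman divisive clustering, cut at maximum modularity.

    Edges of maximal betweenness are removed iteratively (betweenness
    recomputed after each removal); of the partitions traversed, the one
    with the highest modularity is returned.  Deterministic: no seed.
    """
    if G.number_of_nodes() == 0:
        return Partition({}, "edge_betweenness", float("nan"))
    g, nodes = _to_igraph(G)
    dendrogram = g.community_edge_betweenness()
    clusters = dendrogram.as_clustering()  # cut maximising modularity
    return _partition_from_membership(G, nodes, clusters.membership,
                                      "edge_betweenness")


def select_partition(candidates: list, min_module_size: int = 50) -> Partition:
    """Pick the highest-modularity partition and drop small modules.

    Exact ties go to the fixed preference order multilevel >
    label_propagation > edge_betweenness.  Modules smaller than
    ``min_module_size`` become ``"unassigned"``; survivors are renumbered
    m1, m2, ... by descending size (ties by smallest member id).
    """
    if not candidates:
        raise ValueError("no candidate partitions")
    pref = {a: i for i, a in enumerate(_ALGORITHM_PREFERENCE)}
    best = max(candidates,
               key=lambda p: (p.modularity, -pref.get(p.algorithm, 99)))
    sizes = best.module_sizes
    surviving = [m for m, s in sizes.items() if s >= min_module_size]
    if not surviving:
        raise ValueError("all modules fall below the minimum size")
    surviving.sort(key=lambda m: (-sizes[m], min(best.members(m))))
    rename = {m: f"m{i + 1}" for i, m in enumerate(surviving)}
    assignment = {v: rename.get(c, UNASSIGNED)
                  for v, c in best.assignment.items()}
    return Partition(assignment, best.algorithm, best.modularity)
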