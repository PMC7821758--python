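"""Modularity arithmetic, the three detectors, and partition selection."""

import networkx as nx
import numpy as np
import pytest

from coexhub import communities
from coexhub.containers import UNASSIGNED, Partition
from coexhub.reference import exhaustive_best_partition


def two_cliques(k: int) -> nx.Graph:
    G = nx.Graph()
    for base in (0, k):
        G.add_edges_from((base + i, base + j)
                         for i in range(k) for j in range(i + 1, k))
    G.add_edge(0, k)
    return G


TRIANGLES = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


def _modules(p: Partition) -> list:
    groups: dict = {}
    for v, c in p.assignment.items():
        groups.setdefault(c, set()).add(v)
    return sorted(sorted(g) for g in groups.values())


def test_modularity_exact_values():
    assert communities.modularity(TRIANGLES, dict.fromkeys(range(6), 0)) \
        == pytest.approx(0.0, abs=1e-15)
    split = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
    assert communities.modularity(TRIANGLES, split) == pytest.approx(5 / 14)
    tri = nx.complete_graph(3)
    assert communities.modularity(tri, {0: 0, 1: 1, 2: 2}) \
        == pytest.approx(-1 / 3)
    with pytest.raises(ValueError):
        communities.modularity(nx.empty_graph(3), {0: 0, 1: 0, 2: 0})


def test_modularity_agrees_with_networkx_on_random_partitions():
    rng = np.random.default_rng(0)
    for _ in range(20):
        G = nx.gnp_random_graph(12, 0.4, seed=int(rng.integers(1 << 30)))
        if G.number_of_edges() == 0:
            continue
        labels = rng.integers(0, 3, size=12)
        assign = {v: int(labels[v]) for v in G.nodes}
        comms = [{v for v in G.nodes if assign[v] == c}
                 for c in set(labels)]
        comms = [c for c in comms if c]
        assert communities.modularity(G, assign) == pytest.approx(
            nx.community.modularity(G, comms), abs=1e-12)


def test_multilevel_recovers_cliques_and_matches_exhaustive_optimum():
    G8 = two_cliques(4)
    _, q_best = exhaustive_best_partition(G8)
    part = communities.detect_multilevel(G8, seed=0)
    assert part.modularity == pytest.approx(q_best, abs=1e-12)
    assert _modules(part) == [[0, 1, 2, 3], [4, 5, 6, 7]]
    single = communities.detect_multilevel(nx.complete_graph(5), seed=0)
    assert single.n_modules == 1


def test_stored_modularity_matches_recomputation():
    G = two_cliques(5)
    for part in (communities.detect_multilevel(G, seed=1),
                 communities.detect_label_propagation(G, seed=1),
                 communities.detect_edge_betweenness(G)):
        assert part.modularity == pytest.approx(
            communities.modularity(G, part.assignment), abs=1e-12)


def test_label_propagation_recovers_cliques_in_most_seeds():
    G = two_cliques(5)
    target = [list(range(5)), list(range(5, 10))]
    wins = sum(_modules(communities.detect_label_propagation(G, seed=s))
               == target for s in range(10))
    assert wins >= 9


def test_label_propagation_on_edgeless_graph_keeps_singletons():
    G = nx.empty_graph(4)
    part = communities.detect_label_propagation(G, seed=0)
    assert len(set(part.assignment.values())) == 4


def test_edge_betweenness_cuts_bridge_and_handles_single_edge():
    part = communities.detect_edge_betweenness(TRIANGLES)
    assert _modules(part) == [[0, 1, 2], [3, 4, 5]]
    assert part.modularity == pytest.approx(5 / 14)
    single = communities.detect_edge_betweenness(nx.Graph([(0, 1)]))
    assert single.n_modules == 1
    assert single.modularity == pytest.approx(0.0, abs=1e-15)


def test_selection_prefers_highest_modularity_and_filters_small_modules():
    a = Partition({i: 0 for i in range(100)}, "multilevel", 0.6009015)
    b = Partition({i: 0 for i in range(100)}, "label_propagation", 0.3748268)
    c = Partition({i: 0 for i in range(100)}, "edge_betweenness", 0.4815381)
    assert communities.select_partition([a, b, c], 50).algorithm == "multilevel"

    # 3 modules; the 10-gene one is filtered, survivors renumbered by size
    assignment = {f"g{i}": (0 if i < 60 else 1 if i < 130 else 2)
                  for i in range(140)}
    part = Partition(assignment, "multilevel", 0.5)
    sel = communities.select_partition([part], min_module_size=50)
    assert sel.module_sizes == {"m1": 70, "m2": 60}
    assert sel.assignment["g135"] == UNASSIGNED

    with pytest.raises(ValueError):
        communities.select_partition(
            [Partition({0: 0, 1: 1}, "multilevel", 0.1)], 50)
    only = communities.select_partition([part], min_module_size=5)
    assert only.algorithm == "multilevel"
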