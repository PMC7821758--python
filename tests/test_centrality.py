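"""Nine topology scores: pinned conventions, exact micro-oracles, hub union."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import coexhub as cx
from coexhub import centrality, reference

PATH3 = nx.Graph([("a", "b"), ("b", "c")])


def test_ppi_builder_boundary_and_duplicate_collapse():
    edges = pd.DataFrame({
        "protein1": ["a", "a", "b", "b"],
        "protein2": ["b", "c", "c", "c"],
        "combined_score": [400, 399, 350, 600],
    })
    G = cx.build_ppi(edges, min_score=0.400)
    assert G.has_edge("a", "b")          # 400 kept (inclusive)
    assert not G.has_edge("a", "c")      # 399 dropped
    assert G.has_edge("b", "c")          # duplicate collapsed to max=600
    assert G["b"]["c"]["score"] == pytest.approx(0.6)
    # 0-1 scale auto-detected
    G2 = cx.build_ppi(pd.DataFrame({"protein1": ["x"], "protein2": ["y"],
                                    "combined_score": [0.41]}))
    assert G2.has_edge("x", "y")


def test_neighborhood_scores_on_canonical_graphs():
    t = centrality.neighborhood_scores(PATH3)
    assert t.loc["b", "Degree"] == 2
    assert t.loc["b", "MNC"] == 1 and t.loc["b", "DMNC"] == 0.0

    star = nx.star_graph(3)
    s = centrality.neighborhood_scores(star)
    assert s.loc[0, "MNC"] == 1 and s.loc[0, "DMNC"] == 0.0

    tri = nx.complete_graph(3)
    r = centrality.neighborhood_scores(tri)
    assert r.loc[0, "MNC"] == 2
    assert r.loc[0, "DMNC"] == pytest.approx(1 / 2**1.7)


def test_bottleneck_pinned_conventions():
    two = centrality.bottleneck_score(nx.Graph([("a", "b")]))
    assert two.tolist() == [1, 1]        # subtree 1 > 2/4 for each root

    star = nx.star_graph(5)              # center 0, five leaves
    s = centrality.bottleneck_score(star)
    assert s[0] == 5 and all(s[i] == 0 for i in range(1, 6))

    path5 = nx.path_graph(5)
    p = centrality.bottleneck_score(path5)
    assert p[2] == 4


def test_distance_scores_on_paths_and_disconnected_graphs():
    d = centrality.distance_scores(PATH3)
    assert d.loc["b", "Closeness"] == pytest.approx(2.0)
    assert d.loc["a", "Closeness"] == pytest.approx(1.5)
    assert d.loc["b", "Radiality"] == pytest.approx(2.0)
    assert d.loc["a", "Radiality"] == pytest.approx(1.5)

    two_edges = nx.Graph([("a", "b"), ("c", "d")])
    d2 = centrality.distance_scores(two_edges)
    assert (d2["Closeness"] == 1.0).all()


def test_betweenness_and_stress_on_canonical_graphs():
    t = centrality.path_count_scores(PATH3)
    assert t.loc["b", "Betweenness"] == pytest.approx(1.0)
    assert t.loc["b", "Stress"] == pytest.approx(1.0)

    c4 = centrality.path_count_scores(nx.cycle_graph(4))
    assert np.allclose(c4["Betweenness"], 0.5)
    assert np.allclose(c4["Stress"], 1.0)

    star = centrality.path_count_scores(nx.star_graph(6))
    assert star.loc[0, "Betweenness"] == pytest.approx(15.0)  # C(6,2)
    assert star.loc[0, "Stress"] == pytest.approx(15.0)


def test_epc_matches_exact_expectation_and_is_seed_reproducible():
    single = nx.Graph([("a", "b")])
    est = centrality.epc_score(single, replicates=1000, seed=0)
    mean, var = reference.exact_epc(single)
    se = np.sqrt(var / 1000)
    assert (np.abs(est - mean) <= 3 * se).all()

    tri = nx.complete_graph(3)
    est_t = centrality.epc_score(tri, replicates=1000, seed=1)
    mean_t, var_t = reference.exact_epc(tri)
    assert mean_t.iloc[0] == pytest.approx(1.25)  # enumeration oracle
    assert (np.abs(est_t - mean_t) <= 3 * np.sqrt(var_t / 1000)).all()

    again = centrality.epc_score(tri, replicates=1000, seed=1)
    pd.testing.assert_series_equal(est_t, again)

    iso = nx.Graph()
    iso.add_node("z")
    assert centrality.epc_score(iso, replicates=10, seed=0)["z"] == 0.0


def test_top_k_union_hand_example_ties_and_monotonicity():
    scores = pd.DataFrame({"A": [3, 2, 1], "B": [1, 2, 3]},
                          index=["g1", "g2", "g3"])
    hubs = cx.merge_top_k(scores, k=1)
    assert hubs.genes == {"g1", "g3"}
    assert hubs.provenance["g1"] == ["A"]

    assert cx.merge_top_k(scores, k=5).genes == {"g1", "g2", "g3"}

    tied = pd.DataFrame({"A": [5, 4, 4, 1]}, index=list("wxyz"))
    assert cx.merge_top_k(tied, k=2).genes == {"w", "x", "y"}

    rng = np.random.default_rng(9)
    table = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("ABCD"))
    prev: set = set()
    for k in range(1, 8):
        cur = cx.merge_top_k(table, k).genes
        assert prev <= cur
        prev = cur
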