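"""Correlation screen, largest-component extraction, and density."""

import numpy as np
import pandas as pd
import pytest

import coexhub as cx
from coexhub.gcn import correlation_pvalue
from coexhub.synth import SynthConfig


def _frame(rows):
    df = pd.DataFrame(rows).T
    df.index = [f"g{i}" for i in range(df.shape[0])]
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return df


def test_perfect_correlation_and_null_correlation():
    X = _frame({0: [1, 2, 3, 4], 1: [2, 4, 6, 8],      # r = +1
                2: [1, -1, 1, -1], 3: [1, 1, -1, -1]})  # r = 0
    edges = cx.correlation_screen(X, r_min=0.65, alpha=0.05)
    pairs = {frozenset((a, b)) for a, b in zip(edges.gene_a, edges.gene_b)}
    assert frozenset(("g0", "g1")) in pairs
    assert frozenset(("g2", "g3")) not in pairs
    row = edges[(edges.gene_a == "g0") & (edges.gene_b == "g1")].iloc[0]
    assert row.r == pytest.approx(1.0)
    assert row.p == 0.0


def test_small_sample_correlation_oracle():
    """x=(1,2,3,4) vs y=(1,2,3,5): r and p from the explicit t transform."""
    X = _frame({0: [1, 2, 3, 4], 1: [1, 2, 3, 5]})
    edges = cx.correlation_screen(X)
    r_oracle = 6.5 / np.sqrt(5 * 8.75)          # cov / sqrt(var_x var_y)
    p_oracle = float(correlation_pvalue(np.array([r_oracle]), 4)[0])
    assert p_oracle < 0.05                       # edge must be emitted
    assert len(edges) == 1
    assert edges.iloc[0].r == pytest.approx(r_oracle, rel=1e-12)
    assert edges.iloc[0].p == pytest.approx(p_oracle, rel=1e-9)


def test_screen_emits_each_unordered_pair_once_and_no_self_edges():
    rng = np.random.default_rng(1)
    X = _frame({i: rng.normal(size=30) for i in range(15)})
    edges = cx.correlation_screen(X, r_min=0.0, alpha=1.0)
    assert len(edges) == 15 * 14 // 2
    assert (edges.gene_a != edges.gene_b).all()
    pairs = [frozenset((a, b)) for a, b in zip(edges.gene_a, edges.gene_b)]
    assert len(set(pairs)) == len(pairs)


def test_lowering_r_min_only_adds_edges():
    rng = np.random.default_rng(2)
    X = _frame({i: rng.normal(size=12) for i in range(12)})
    strict = cx.correlation_screen(X, r_min=0.6, alpha=1.0)
    loose = cx.correlation_screen(X, r_min=0.3, alpha=1.0)
    strict_pairs = {frozenset((a, b))
                    for a, b in zip(strict.gene_a, strict.gene_b)}
    loose_pairs = {frozenset((a, b))
                   for a, b in zip(loose.gene_a, loose.gene_b)}
    assert strict_pairs <= loose_pairs


def test_constant_gene_is_excluded_with_warning():
    X = _frame({0: [1, 2, 3, 4], 1: [5, 5, 5, 5]})
    with pytest.warns(UserWarning, match="constant"):
        edges = cx.correlation_screen(X, r_min=0.0, alpha=1.0)
    assert len(edges) == 0


def test_largest_component_is_selected():
    edges = pd.DataFrame({"gene_a": ["a", "c", "d"],
                          "gene_b": ["b", "d", "e"],
                          "r": [0.9, 0.9, 0.9], "p": [0.0, 0.0, 0.0]})
    G, summary = cx.extract_gcn(edges)
    assert set(G.nodes) == {"c", "d", "e"}
    assert summary["size"].tolist() == [3, 2]


def test_single_component_returns_whole_graph():
    edges = pd.DataFrame({"gene_a": ["a", "b"], "gene_b": ["b", "c"],
                          "r": [0.9, -0.9], "p": [0.0, 0.0]})
    G, _ = cx.extract_gcn(edges)
    assert set(G.nodes) == {"a", "b", "c"}
    assert G["b"]["c"]["sign"] == -1


def test_density_of_complete_empty_and_published_scale_graphs():
    import networkx as nx
    assert cx.network_density(nx.complete_graph(4)) == 1.0
    empty = nx.Graph()
    empty.add_nodes_from(range(3))
    assert cx.network_density(empty) == 0.0
    with pytest.raises(ValueError):
        cx.network_density(nx.Graph())
    # arithmetic inversion of a published network density: n=2583 nodes
    # at density 0.01704045 implies m = 56,824 edges
    G = nx.empty_graph(2583)
    assert 2 * 56824 / (2583 * 2582) == pytest.approx(0.01704045, abs=5e-8)


def test_planted_block_pairs_become_edges():
    """Strong within-block pairs (joint loading >= 0.72) are recovered."""
    fractions = []
    for seed in range(10):
        cfg = SynthConfig(seed=seed)
        expr, truth = cx.generate_expression(cfg)
        lam = truth.loadings
        edges = cx.correlation_screen(
            expr.tumor_values.loc[truth.module_of_gene[
                truth.module_of_gene >= 0].index])
        pairs = {frozenset((a, b))
                 for a, b in zip(edges.gene_a, edges.gene_b)}
        hit = n = 0
        for b in range(len(cfg.module_sizes)):
            members = [g for g in truth.module_genes(b)
                       if lam.loc[g, b] > 0]
            for i, g in enumerate(members):
                for h in members[i + 1:]:
                    if lam.loc[g, b] * lam.loc[h, b] >= 0.72:
                        n += 1
                        hit += frozenset((g, h)) in pairs
        fractions.append(hit / n)
    assert np.median(fractions) >= 0.95
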