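"""Thresholded Pearson co-expression network over tumor-sample DEGs.

Edges join gene pairs whose tumor-sample Pearson correlation satisfies
|r| >= r_min with two-sided p < alpha, where p comes from the exact t
transform ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` with n - 2 degrees of
freedom.  The gene co-expression network (GCN) is the largest connected
component of the resulting graph.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["correlation_screen", "extract_gcn", "network_density",
           "correlation_pvalue"]


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r at sample size n via the t transform."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def correlation_screen(X_tumor: pd.DataFrame, r_min: float = 0.65,
                       alpha: float = 0.05,
                       block_size: int = 2000) -> pd.DataFrame:
    """Screen all unordered gene pairs for strong tumor co-expression.

    Parameters
    ----------
    X_tumor : DataFrame
        Genes x tumor samples (typically restricted to DEGs).
    r_min, alpha : float
        Absolute-correlation and p-value cut-offs (|r| >= r_min, p < alpha).
    block_size : int
        Row-block width for the pairwise scan, keeping memory linear in the
        emitted edges rather than quadratic in genes.

    Returns an edge table (gene_a, gene_b, r, p) with the correlation sign
    retained in ``r``; constant genes are excluded with a warning.
    """
    n = X_tumor.shape[1]
    if n < 3:
        raise ValueError("need at least 3 tumor samples")
    sd = X_tumor.std(axis=1, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"{len(constant)} constant genes excluded from the screen")
        X_tumor = X_tumor.drop(index=constant)
    genes = X_tumor.index.to_list()
    M = X_tumor.to_numpy(dtype=float)
    M = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(M, axis=1)
    M = M / norms[:, None]

    rows = []
    for start in range(0, len(genes), block_size):
        stop = min(start + block_size, len(genes))
        R = M[start:stop] @ M.T  # (block x all)
        for bi in range(stop - start):
            i = start + bi
            r_row = np.clip(R[bi, i + 1:], -1.0, 1.0)
            hit = np.abs(r_row) >= r_min
            if not hit.any():
                continue
            js = np.nonzero(hit)[0] + i + 1
            r_hit = r_row[hit]
            p_hit = correlation_pvalue(r_hit, n)
            for j, r, p in zip(js, r_hit, p_hit):
                if p < alpha:
                    rows.append((genes[i], genes[j], float(r), float(p)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p"])


def extract_gcn(edges: pd.DataFrame) -> tuple[nx.Graph, pd.DataFrame]:
    """Build the graph and return its largest connected component.

    Ties on component size break deterministically toward the component
    containing the lexicographically smallest gene id.  Also returns a
    component-size table (component rank, size, smallest member).
    """
    G = nx.Graph()
    for row in edges.itertuples(index=False):
        G.add_edge(row.gene_a, row.gene_b, r=row.r, p=row.p,
                   sign=1 if row.r >= 0 else -1)
    if G.number_of_edges() == 0:
        warnings.warn("empty edge set: GCN is empty")
        return nx.Graph(), pd.DataFrame(columns=["size", "smallest_member"])
    comps = sorted(nx.connected_components(G),
                   key=lambda c: (-len(c), min(c)))
    summary = pd.DataFrame(
        [(len(c), min(c)) for c in comps],
        columns=["size", "smallest_member"],
    )
    return G.subgraph(comps[0]).copy(), summary


def network_density(G: nx.Graph) -> float:
    """Edge density 2m / (n(n-1)); undefined below two nodes."""
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for graphs with fewer than 2 nodes")
    return 2.0 * G.number_of_edges() / (n * (n - 1))
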