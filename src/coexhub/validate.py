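"""Hub-gene validation: independent-cohort t-tests, ROC/AUC, methylation
differences, and hypergeometric over-representation analysis.

AUC is computed from the Mann-Whitney U statistic (ties counted one half),
so it equals the probability that a random tumor value exceeds a random
normal value; the attached p-value is the two-sided normal approximation
of the rank-sum statistic with tie correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, MethylationData

__all__ = ["validate_de", "roc_auc", "methylation_test",
           "ora_hypergeometric", "RocResult"]


def validate_de(X_test: ExpressionMatrix, genes, alpha: float = 0.05,
                paired: bool = False) -> pd.DataFrame:
    """Per-gene t-test of tumor vs normal on an independent expression set.

    Unpaired unequal-variance by default; ``paired`` assumes tumor and
    normal columns are matched in order.  Genes absent from ``X_test`` are
    reported with NaN rather than failing.  Direction (up/down/none) is by
    mean comparison, called only below ``alpha``.
    """
    tum, nor = X_test.tumor_values, X_test.normal_values
    rows = []
    for g in genes:
        if g not in X_test.gene_ids:
            rows.append((g, np.nan, "missing"))
            continue
        a, b = tum.loc[g].to_numpy(), nor.loc[g].to_numpy()
        if paired:
            if len(a) != len(b):
                raise ValueError("paired test needs equal group sizes")
            p = float(stats.ttest_rel(a, b).pvalue)
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0
        direction = "none"
        if p < alpha:
            direction = "up" if a.mean() > b.mean() else "down"
        rows.append((g, p, direction))
    return pd.DataFrame(rows, columns=["gene", "p_value", "direction"]) \
             .set_index("gene")


@dataclass
class RocResult:
    auc: float
    p_value: float
    n_pos: int
    n_neg: int


def roc_auc(values, labels, positive="tumor") -> RocResult:
    """AUC via the Mann-Whitney U statistic, ties counted one half.

    ``labels`` marks each observation; ``positive`` names the class whose
    larger values should drive AUC above 0.5.  AUC below 0.5 is reported
    as-is (no flipping).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == positive]
    neg = values[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided",
                             method="asymptotic")
    auc = float(res.statistic) / (len(pos) * len(neg))
    return RocResult(auc, float(res.pvalue), len(pos), len(neg))


def methylation_test(M: MethylationData, alpha: float = 0.05,
                     paired: bool = True) -> pd.DataFrame:
    """Per-gene tumor-vs-normal beta comparison with hypo/hyper calls.

    Paired t-test by default using the pairing table; a broken pairing
    falls back to an unpaired Welch test with a warning.  A gene is called
    hypomethylated when its tumor mean is below the normal mean with
    p < alpha (hypermethylated for the reverse).
    """
    t_cols = list(M.pairing["tumor_sample"])
    n_cols = list(M.pairing["normal_sample"])
    ok = all(c in M.values.columns for c in t_cols + n_cols)
    if paired and not ok:
        warnings.warn("pairing table inconsistent; falling back to unpaired test")
        paired = False
    if not ok:
        t_cols = [c for c in t_cols if c in M.values.columns]
        n_cols = [c for c in n_cols if c in M.values.columns]
    tum = M.values[t_cols].to_numpy()
    nor = M.values[n_cols].to_numpy()
    if paired:
        p = stats.ttest_rel(tum, nor, axis=1).pvalue
    else:
        p = stats.ttest_ind(tum, nor, axis=1, equal_var=False).pvalue
    p = np.where(np.isnan(p), 1.0, p)
    mt, mn = tum.mean(axis=1), nor.mean(axis=1)
    call = np.where((p < alpha) & (mt < mn), "hypomethylation",
                    np.where((p < alpha) & (mt > mn), "hypermethylation",
                             "none"))
    return pd.DataFrame({"mean_tumor_beta": mt, "mean_normal_beta": mn,
                         "p_value": p, "call": call}, index=M.values.index)


def ora_hypergeometric(query, gene_sets: dict, universe,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of a query gene set in named collections.

    For each set S the upper-tail hypergeometric probability
    P(X >= k) with k = |query & S|, K = |S & universe|, n = |query|,
    N = |universe| is computed; Benjamini-Hochberg adjusted p-values are
    reported alongside.  Rows are sorted by ascending p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        S = set(members) & universe
        K = len(S)
        k = len(query & S)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p_value"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["p_value"] < alpha
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return out
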