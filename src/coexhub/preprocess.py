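"""Expression preprocessing: low-expression filter, outlier removal, DEGs.

The differential-expression rule is the classic two-criterion fold-change /
t-test screen: a gene is up-regulated when its tumor/normal FPKM-mean ratio
is >= ``fc_up`` (down when <= ``fc_down``) with a two-sided t-test p-value
below ``alpha``.  Thresholds are inclusive on the fold change and strict on
the p-value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = ["filter_low_expression", "detect_outlier_samples", "identify_degs"]

#: pseudocount guarding fold-change division by zero (genes are normally
#: pre-filtered by max-FPKM so it rarely matters)
FC_PSEUDOCOUNT = 1e-3


def filter_low_expression(X: ExpressionMatrix,
                          min_max_fpkm: float = 1.0) -> ExpressionMatrix:
    """Drop genes whose maximum FPKM is below threshold in both groups.

    A gene is retained iff its maximum over tumor samples OR over normal
    samples is >= ``min_max_fpkm`` (the boundary value is kept).  Gene
    order is preserved.
    """
    keep = (X.tumor_values.max(axis=1) >= min_max_fpkm) | (
        X.normal_values.max(axis=1) >= min_max_fpkm
    )
    if not keep.any():
        warnings.warn("low-expression filter removed every gene")
    return ExpressionMatrix(X.values.loc[keep], X.groups)


def detect_outlier_samples(X: ExpressionMatrix,
                           min_cluster_frac: float = 0.05,
                           max_rounds: int = 5) -> list:
    """Flag outlying tumor samples by iterative hierarchical clustering.

    Tumor samples are clustered (complete linkage, Euclidean distance over
    gene vectors) and the dendrogram cut into two clusters; when the
    smaller cluster holds fewer than ``min_cluster_frac`` of the current
    samples its members are flagged and the procedure recurses on the
    remainder, for at most ``max_rounds`` rounds.  Returns flagged sample
    ids in flag order.
    """
    current = list(X.tumor_samples)
    if len(current) < 4:
        warnings.warn("fewer than 4 tumor samples; outlier detection skipped")
        return []
    flagged: list = []
    for _ in range(max_rounds):
        if len(current) < 4:
            break
        M = X.values[current].T.to_numpy()
        Z = linkage(M, method="complete", metric="euclidean")
        labels = fcluster(Z, t=2, criterion="maxclust")
        sizes = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
        if len(sizes) < 2:
            break
        small = min(sizes, key=lambda lab: (sizes[lab], lab))
        if sizes[small] >= min_cluster_frac * len(current):
            break
        out = [s for s, lab in zip(current, labels) if lab == small]
        flagged.extend(out)
        current = [s for s in current if s not in set(out)]
    return flagged


def _welch_p(t_vals: pd.DataFrame, n_vals: pd.DataFrame,
             equal_var: bool) -> np.ndarray:
    res = stats.ttest_ind(t_vals.to_numpy(), n_vals.to_numpy(), axis=1,
                          equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: p=1 when means agree, ~0 otherwise
    nan = np.isnan(p)
    if nan.any():
        same = np.isclose(t_vals.to_numpy()[nan].mean(axis=1),
                          n_vals.to_numpy()[nan].mean(axis=1))
        p[nan] = np.where(same, 1.0, 0.0)
    return p


def identify_degs(X: ExpressionMatrix, fc_up: float = 2.0,
                  fc_down: float = 0.5, alpha: float = 0.05,
                  log_transform: bool = False, equal_var: bool = False,
                  bh_correct: bool = False) -> pd.DataFrame:
    """Two-criterion (fold-change + t-test) differential expression screen.

    Fold change is the ratio of group FPKM means (tumor/normal, with a
    small pseudocount); the p-value comes from a two-sided
    unequal-variance (Welch) t-test, optionally on log2(x+1)-transformed
    values, optionally pooled-variance (``equal_var``) or
    Benjamini-Hochberg adjusted (``bh_correct``).

    Returns a DataFrame indexed by gene with columns ``fold_change``,
    ``p_value`` and ``direction`` in {up, down, none}.
    """
    tum, nor = X.tumor_values, X.normal_values
    if tum.shape[1] < 2 or nor.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    mean_t, mean_n = tum.mean(axis=1), nor.mean(axis=1)
    # pseudocount only guards zero denominators, keeping the inclusive
    # fold-change boundary exact for ordinary values
    fold = pd.Series(
        np.where(mean_n > 0, mean_t / mean_n.replace(0, np.nan),
                 (mean_t + FC_PSEUDOCOUNT) / FC_PSEUDOCOUNT),
        index=mean_t.index)
    if log_transform:
        p = _welch_p(np.log2(tum + 1), np.log2(nor + 1), equal_var)
    else:
        p = _welch_p(tum, nor, equal_var)
    p_eff = multipletests(p, method="fdr_bh")[1] if bh_correct else p
    direction = np.where((fold >= fc_up) & (p_eff < alpha), "up",
                         np.where((fold <= fc_down) & (p_eff < alpha),
                                  "down", "none"))
    return pd.DataFrame({"fold_change": fold, "p_value": p,
                         "direction": direction}, index=X.gene_ids)
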