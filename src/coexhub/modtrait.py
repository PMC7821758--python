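"""Module eigengenes, trait association, Cox PS-values, key-module choice.

The module eigengene (ME) is the first principal-component score vector of
a module's samples x genes expression submatrix, unit-normalised and
sign-oriented so it correlates non-negatively with the module's mean
centred expression.  MEs are Pearson-correlated with the clinical
indicators event, T, N and M.  Prognostic significance of a gene is
PS = -log10(p) of its univariate Cox proportional-hazards fit on
log2(FPKM + 1) expression; a module's PS-value is the exact sum of its
members' PS-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .containers import UNASSIGNED, ExpressionMatrix, Partition

__all__ = ["module_eigengene", "trait_association", "cox_ps", "ps_value",
           "select_key_module", "PSResult", "KeyModuleSelection",
           "INDICATORS"]

INDICATORS = ("event", "T", "N", "M")


def ps_value(p) -> np.ndarray:
    """Prognostic significance: PS = -log10(p), clipped away from p = 0."""
    return -np.log10(np.clip(p, 1e-300, 1.0))


def module_eigengene(X_tumor: pd.DataFrame, members, *,
                     scale_genes: bool = False) -> pd.Series:
    """First principal-component score vector over tumor samples.

    ``X_tumor`` is genes x tumor samples; genes are mean-centred
    (optionally unit-variance scaled) and the leading left singular vector
    of the samples x genes matrix, normalised to unit length and oriented
    toward the module's mean expression, is returned (one value per
    sample).  An all-constant module yields a zero vector with a warning.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("a module eigengene needs at least 2 genes")
    M = X_tumor.loc[members].T.to_numpy(dtype=float)  # samples x genes
    if M.shape[0] < 3:
        raise ValueError("need at least 3 tumor samples")
    M = M - M.mean(axis=0, keepdims=True)
    if scale_genes:
        sd = M.std(axis=0, ddof=1)
        M = M / np.where(sd > 0, sd, 1.0)
    if not np.any(M):
        warnings.warn("all-constant module: eigengene is the zero vector")
        return pd.Series(np.zeros(M.shape[0]), index=X_tumor.columns)
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    me = u[:, 0]
    if me @ M.mean(axis=1) < 0:
        me = -me
    return pd.Series(me, index=X_tumor.columns, name="ME")


def compute_eigengenes(expr: ExpressionMatrix, partition: Partition,
                       **kwargs) -> pd.DataFrame:
    """MEs for every surviving module: tumor samples x modules."""
    X = expr.tumor_values
    mes = {m: module_eigengene(X, partition.members(m), **kwargs)
           for m in sorted(partition.module_sizes)}
    return pd.DataFrame(mes)


def trait_association(mes: pd.DataFrame, clin: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p between each ME and each indicator.

    ``mes`` is samples x modules; ``clin`` is indexed by sample with
    columns event, T (ordinal 1-4), N, M.  Pairwise-complete samples are
    used; a constant indicator yields NaN.  Returns a tidy frame
    (module, indicator, r, p).
    """
    rows = []
    common = mes.index.intersection(clin.index)
    for module in mes.columns:
        for ind in INDICATORS:
            x = mes.loc[common, module].astype(float)
            y = clin.loc[common, ind].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or y[ok].nunique() < 2 or x[ok].nunique() < 2:
                rows.append((module, ind, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append((module, ind, float(r), float(p)))
    return pd.DataFrame(rows, columns=["module", "indicator", "r", "p"])


@dataclass
class PSResult:
    """Per-gene Cox p-values / PS-values and per-module PS sums."""

    gene_table: pd.DataFrame  # columns: module, p, ps
    ps_module: pd.Series

    @property
    def ps_gene(self) -> pd.Series:
        return self.gene_table["ps"]


def cox_ps(expr: ExpressionMatrix, clin: pd.DataFrame,
           partition: Partition) -> PSResult:
    """Univariate Cox screening of all module genes, aggregated by module.

    Each assigned gene is fitted with a proportional-hazards model on
    log2(FPKM + 1) tumor expression against (time, status); the Wald
    two-sided p gives PS = -log10(p).  Non-converged fits get p = 1
    (PS = 0) with a warning.  Module PS is the exact member sum.
    """
    samples = expr.tumor_samples.intersection(clin.index)
    sub = clin.loc[samples]
    ok = sub["time"].notna() & sub["status"].notna()
    samples, sub = samples[ok], sub[ok]
    if len(samples) < 10:
        raise ValueError("need time/status for at least 10 samples")
    if sub["status"].sum() == 0:
        raise ValueError("no events: the partial likelihood is degenerate")

    genes = [g for g, m in partition.assignment.items() if m != UNASSIGNED]
    genes = [g for g in genes if g in expr.gene_ids]
    X = np.log2(expr.values.loc[genes, samples] + 1.0)
    base = pd.DataFrame({"time": sub["time"].to_numpy(),
                         "status": sub["status"].to_numpy()},
                        index=samples)
    rows = []
    n_failed = 0
    for g in genes:
        df = base.copy()
        df["x"] = X.loc[g].to_numpy()
        if df["x"].nunique() < 2:
            rows.append((g, 1.0))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter = CoxPHFitter()
                fitter.fit(df, duration_col="time", event_col="status")
            rows.append((g, float(fitter.summary.loc["x", "p"])))
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            rows.append((g, 1.0))
    if n_failed:
        warnings.warn(f"{n_failed} Cox fits did not converge; assigned p=1")

    table = pd.DataFrame(rows, columns=["gene", "p"]).set_index("gene")
    table["module"] = [partition.assignment[g] for g in table.index]
    table["ps"] = ps_value(table["p"])
    ps_module = table.groupby("module")["ps"].sum()
    return PSResult(table[["module", "p", "ps"]], ps_module)


@dataclass
class KeyModuleSelection:
    key_module: str
    by_trait: str
    by_ps: str | None
    agree: bool


def select_key_module(trait_cor: pd.DataFrame,
                      ps_module: pd.Series | None = None,
                      module_sizes: dict | None = None) -> KeyModuleSelection:
    """Key module = strongest absolute ME-indicator correlation.

    The module whose maximum |r| over the four indicators is largest wins
    (ties toward the larger module, then smallest id).  When the PS-value
    argmax differs, a disagreement warning is logged and both are
    reported; the trait choice stands.
    """
    scores = trait_cor.assign(abs_r=trait_cor["r"].abs()) \
                      .groupby("module")["abs_r"].max().dropna()
    if scores.empty:
        raise ValueError("no module has a defined trait correlation")
    sizes = module_sizes or {}
    by_trait = min(scores.index,
                   key=lambda m: (-scores[m], -sizes.get(m, 0), str(m)))
    by_ps = None
    agree = True
    if ps_module is not None and len(ps_module):
        by_ps = ps_module.idxmax()
        agree = by_ps == by_trait
        if not agree:
            warnings.warn(
                f"trait ({by_trait}) and PS-value ({by_ps}) criteria disagree"
            )
    return KeyModuleSelection(by_trait, by_trait, by_ps, agree)
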