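"""Core in-memory containers shared across pipeline stages.

The pipeline passes around a small number of typed objects: a labelled
expression matrix (genes x samples with tumor/normal groups), a flat node
partition with its modularity, and the planted ground truth emitted by the
synthetic-data generator.  Tabular intermediates (DEG tables, edge lists,
score tables) are plain pandas DataFrames with documented columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """Non-negative abundance matrix (genes x samples) with group labels.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene id, columns by sample id; FPKM-like scale.
    groups : Series
        Maps every sample id to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a tumor/normal label")
        bad = set(self.groups.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def tumor_samples(self) -> pd.Index:
        return self.groups.index[self.groups == TUMOR]

    @property
    def normal_samples(self) -> pd.Index:
        return self.groups.index[self.groups == NORMAL]

    @property
    def tumor_values(self) -> pd.DataFrame:
        return self.values[self.tumor_samples]

    @property
    def normal_values(self) -> pd.DataFrame:
        return self.values[self.normal_samples]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.groups)

    def drop_samples(self, samples) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if s not in set(samples)]
        return ExpressionMatrix(self.values[keep], self.groups.loc[keep])


UNASSIGNED = "unassigned"


@dataclass
class Partition:
    """Flat assignment of network nodes to modules.

    ``assignment`` maps node -> module label; the special label
    ``"unassigned"`` marks nodes whose module was filtered out (kept so
    downstream joins stay total).  ``modularity`` is Newman's Q of the
    partition on the graph it was detected on.
    """

    assignment: dict
    algorithm: str
    modularity: float

    @property
    def module_sizes(self) -> dict:
        sizes = Counter(m for m in self.assignment.values() if m != UNASSIGNED)
        return dict(sizes)

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def members(self, module) -> list:
        return [n for n, m in self.assignment.items() if m == module]

    def as_series(self) -> pd.Series:
        return pd.Series(self.assignment, name="module")


@dataclass
class TruthBundle:
    """Planted ground truth for recovery testing of synthetic data.

    module_of_gene maps every gene to a planted block index (-1 for
    background); deg_labels to {up, down, none}; methyl_changed to
    {hypo, hyper, none}.  latent_factors holds the per-tumor-sample block
    factors the generator drew (samples x blocks), which downstream
    clinical/survival generation conditions on.
    """

    module_of_gene: pd.Series
    deg_labels: pd.Series
    prognostic_module: int
    hub_genes: list
    methyl_changed: pd.Series
    latent_factors: pd.DataFrame
    #: planted factor loadings (genes x blocks); zero rows for background
    loadings: pd.DataFrame | None = None

    def module_genes(self, module: int) -> list:
        return list(self.module_of_gene.index[self.module_of_gene == module])


@dataclass
class MethylationData:
    """Beta-value matrix (genes x samples) with tumor/normal pairing.

    ``pairing`` has one row per patient: columns pair_id, tumor_sample,
    normal_sample.
    """

    values: pd.DataFrame
    pairing: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if ((v <= 0) | (v >= 1)).any():
            raise ValueError("beta values must lie strictly in (0, 1)")
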