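"""End-to-end orchestration: preprocess -> GCN -> modules -> traits ->
hubs -> validation, with one config, one seed, and a run report.

:func:`analyze` is the in-memory core used by tests and scripts;
:func:`run_pipeline` wraps it with file I/O and artifact writing.  The
global seed fans out to per-stage sub-seeds by fixed offsets so every
stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import centrality, communities, gcn, io, modtrait, preprocess, validate
from .containers import ExpressionMatrix, MethylationData, Partition

__all__ = ["RunConfig", "AnalysisResult", "analyze", "run_pipeline"]

# per-stage seed offsets
_SEED_MULTILEVEL, _SEED_LPA, _SEED_EPC = 11, 13, 17


@dataclass
class RunConfig:
    """Paths, stage thresholds, and the global seed for one run.

    Threshold defaults are the pipeline's standard operating point:
    max-FPKM filter at 1, fold-change cuts 2 / 0.5 with alpha 0.05,
    |r| >= 0.65 correlation screen, 50-gene minimum module size, PPI
    confidence >= 0.400, top-5 hub union, 1000 EPC replicates at
    retention 0.5.
    """

    expr_path: str = ""
    labels_path: str = ""
    clinical_path: str = ""
    ppi_path: str = ""
    test_expr_path: str | None = None
    test_labels_path: str | None = None
    methylation_path: str | None = None
    methyl_pairing_path: str | None = None
    gene_sets_path: str | None = None
    out_dir: str = "coexhub_out"

    min_max_fpkm: float = 1.0
    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    r_min: float = 0.65
    min_module_size: int = 50
    ppi_min_score: float = 0.400
    top_k: int = 5
    epc_replicates: int = 1000
    epc_retain_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.r_min <= 1
                and 0 <= self.epc_retain_p <= 1):
            raise ValueError("threshold out of range")
        if self.fc_up < 1 or not 0 < self.fc_down <= 1:
            raise ValueError("fold-change cuts out of range")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class AnalysisResult:
    """Every intermediate and final product of one pipeline run."""

    filtered: ExpressionMatrix
    outliers: list
    degs: pd.DataFrame
    edges: pd.DataFrame
    gcn_graph: object
    component_sizes: pd.DataFrame
    gcn_density: float
    partitions: list
    selected: Partition
    module_densities: dict
    eigengenes: pd.DataFrame
    trait_cor: pd.DataFrame
    ps: modtrait.PSResult
    key: modtrait.KeyModuleSelection
    ppi_graph: object
    scores: pd.DataFrame
    hubs: centrality.HubSet
    validation: pd.DataFrame | None = None
    roc: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None

    def report(self, seed: int, config: dict | None = None) -> dict:
        degs = self.degs
        n_up = int((degs["direction"] == "up").sum())
        n_down = int((degs["direction"] == "down").sum())
        sizes = self.selected.module_sizes
        return {
            "seed": seed,
            "n_genes_after_filter": int(self.filtered.values.shape[0]),
            "outlier_samples": list(self.outliers),
            "n_degs": n_up + n_down,
            "n_up": n_up,
            "n_down": n_down,
            "n_edges": int(len(self.edges)),
            "gcn_size": int(self.gcn_graph.number_of_nodes()),
            "gcn_density": self.gcn_density,
            "modularity": {p.algorithm: p.modularity for p in self.partitions},
            "selected_algorithm": self.selected.algorithm,
            "module_sizes": {str(k): int(v) for k, v in sorted(sizes.items())},
            "module_densities": self.module_densities,
            "key_module": self.key.key_module,
            "key_module_by_ps": self.key.by_ps,
            "hub_genes": {g: a for g, a in sorted(self.hubs.provenance.items())},
            "config": config or {},
        }


def analyze(expr: ExpressionMatrix, clinical: pd.DataFrame,
            ppi_edges: pd.DataFrame, config: RunConfig | None = None,
            *, test_expr: ExpressionMatrix | None = None,
            methylation: MethylationData | None = None,
            gene_sets: dict | None = None) -> AnalysisResult:
    """Run the full analysis in memory and return every intermediate."""
    cfg = config or RunConfig()
    seed = int(cfg.seed)

    # --- preprocess ---------------------------------------------------
    filtered = preprocess.filter_low_expression(expr, cfg.min_max_fpkm)
    outliers = preprocess.detect_outlier_samples(filtered)
    if outliers:
        filtered = filtered.drop_samples(outliers)
    degs = preprocess.identify_degs(filtered, cfg.fc_up, cfg.fc_down,
                                    cfg.alpha)
    de_genes = degs.index[degs["direction"] != "none"]
    if len(de_genes) < 2:
        raise RuntimeError("preprocess stage produced fewer than 2 DEGs")

    # --- co-expression network ---------------------------------------
    edges = gcn.correlation_screen(
        filtered.tumor_values.loc[de_genes], cfg.r_min, cfg.alpha)
    graph, comp_sizes = gcn.extract_gcn(edges)
    if graph.number_of_nodes() < 2:
        raise RuntimeError("gcn stage produced an empty network")
    density = gcn.network_density(graph)

    # --- module detection --------------------------------------------
    partitions = [
        communities.detect_multilevel(graph, seed=seed + _SEED_MULTILEVEL),
        communities.detect_label_propagation(graph, seed=seed + _SEED_LPA),
        communities.detect_edge_betweenness(graph),
    ]
    selected = communities.select_partition(partitions, cfg.min_module_size)
    module_densities = {
        m: gcn.network_density(graph.subgraph(selected.members(m)))
        for m in sorted(selected.module_sizes)
    }

    # --- trait & survival association --------------------------------
    mes = modtrait.compute_eigengenes(filtered, selected)
    trait_cor = modtrait.trait_association(mes, clinical)
    ps = modtrait.cox_ps(filtered, clinical, selected)
    key = modtrait.select_key_module(trait_cor, ps.ps_module,
                                     selected.module_sizes)

    # --- hub genes on the PPI network --------------------------------
    key_genes = set(selected.members(key.key_module))
    sub_edges = ppi_edges[ppi_edges["protein1"].isin(key_genes)
                          & ppi_edges["protein2"].isin(key_genes)]
    ppi_graph = centrality.build_ppi(sub_edges, cfg.ppi_min_score)
    if ppi_graph.number_of_nodes() == 0:
        raise RuntimeError("centrality stage received an empty PPI network")
    scores = centrality.score_table(
        ppi_graph, epc_replicates=cfg.epc_replicates,
        epc_retain_p=cfg.epc_retain_p, seed=seed + _SEED_EPC)
    hubs = centrality.merge_top_k(scores, cfg.top_k)

    # --- optional validation stages -----------------------------------
    result = AnalysisResult(
        filtered, outliers, degs, edges, graph, comp_sizes, density,
        partitions, selected, module_densities, mes, trait_cor, ps, key,
        ppi_graph, scores, hubs)
    hub_genes = sorted(hubs.genes)
    if test_expr is not None:
        result.validation = validate.validate_de(test_expr, hub_genes,
                                                 cfg.alpha)
        rocs = []
        for g in hub_genes:
            if g not in test_expr.gene_ids:
                continue
            rr = validate.roc_auc(test_expr.values.loc[g],
                                  test_expr.groups.to_numpy())
            rocs.append((g, rr.auc, rr.p_value, rr.n_pos, rr.n_neg))
        result.roc = pd.DataFrame(
            rocs, columns=["gene", "auc", "p_value", "n_pos", "n_neg"]
        ).set_index("gene")
    if methylation is not None:
        present = [g for g in hub_genes if g in methylation.values.index]
        sub = MethylationData(methylation.values.loc[present],
                              methylation.pairing)
        result.methylation = validate.methylation_test(sub, cfg.alpha)
    if gene_sets:
        universe = set(filtered.gene_ids)
        query = set(hub_genes) & universe
        result.enrichment = validate.ora_hypergeometric(
            query, gene_sets, universe, cfg.alpha)
    return result


def run_pipeline(config: RunConfig) -> dict:
    """File-based run: load inputs, analyze, write artifacts + report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression(config.expr_path, config.labels_path)
    clinical = io.read_clinical(config.clinical_path)
    ppi_edges = io.read_edge_list(config.ppi_path)
    test_expr = None
    if config.test_expr_path and config.test_labels_path:
        test_expr = io.read_expression(config.test_expr_path,
                                       config.test_labels_path)
    methylation = None
    if config.methylation_path and config.methyl_pairing_path:
        methylation = io.read_methylation(config.methylation_path,
                                          config.methyl_pairing_path)
    gene_sets = io.read_gmt(config.gene_sets_path) \
        if config.gene_sets_path else None

    res = analyze(expr, clinical, ppi_edges, config, test_expr=test_expr,
                  methylation=methylation, gene_sets=gene_sets)

    res.degs.rename_axis("gene").to_csv(out / "degs.tsv", sep="\t")
    res.edges.to_csv(out / "gcn_edges.tsv", sep="\t", index=False)
    res.component_sizes.to_csv(out / "component_sizes.tsv", sep="\t",
                               index=False)
    part = res.selected.as_series().rename_axis("gene").reset_index()
    part["algorithm"] = res.selected.algorithm
    part.to_csv(out / "modules.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(p.algorithm, p.modularity, p.n_modules) for p in res.partitions],
        columns=["algorithm", "modularity", "n_modules"],
    ).to_csv(out / "modularity.tsv", sep="\t", index=False)
    res.eigengenes.rename_axis("sample_id").to_csv(out / "eigengenes.tsv",
                                                   sep="\t")
    res.trait_cor.to_csv(out / "trait_correlation.tsv", sep="\t", index=False)
    ps_out = res.ps.gene_table.rename_axis("gene")
    ps_out.to_csv(out / "ps_values.tsv", sep="\t")
    res.ps.ps_module.rename("ps_module").rename_axis("module") \
        .to_csv(out / "ps_modules.tsv", sep="\t")
    res.scores.rename_axis("gene").to_csv(out / "hub_scores.tsv", sep="\t")
    res.hubs.as_frame().to_csv(out / "hubs.tsv", sep="\t", index=False)
    for name in ("validation", "roc", "methylation", "enrichment"):
        table = getattr(res, name)
        if table is not None:
            table.to_csv(out / f"{name}.tsv", sep="\t")

    report = res.report(config.seed, asdict(config))
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
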