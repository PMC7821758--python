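"""Readers and writers for the pipeline's plain-text table formats.

All tables are tab-separated with a header row: expression (genes x
samples) plus a two-column sample-label table, clinical tables, STRING-
export-style scored edge lists, methylation beta matrices with a pairing
table, GMT gene-set files, and the planted-truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, MethylationData, TruthBundle

__all__ = [
    "read_expression", "write_expression", "read_clinical", "write_clinical",
    "read_edge_list", "write_edge_list", "read_methylation",
    "write_methylation", "read_gmt", "write_truth", "read_truth",
]


def read_expression(expr_path, labels_path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t")
    groups = labels.set_index("sample_id")["group"]
    return ExpressionMatrix(values, groups)


def write_expression(X: ExpressionMatrix, expr_path, labels_path) -> None:
    X.values.to_csv(expr_path, sep="\t")
    X.groups.rename_axis("sample_id").rename("group").reset_index() \
        .to_csv(labels_path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_clinical(clin: pd.DataFrame, path) -> None:
    clin.rename_axis("sample_id").to_csv(path, sep="\t")


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return df[["protein1", "protein2", "combined_score"]]


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_methylation(values_path, pairing_path) -> MethylationData:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    pairing = pd.read_csv(pairing_path, sep="\t")
    return MethylationData(values, pairing)


def write_methylation(M: MethylationData, values_path, pairing_path) -> None:
    M.values.to_csv(values_path, sep="\t")
    M.pairing.to_csv(pairing_path, sep="\t", index=False)


def read_gmt(path) -> dict:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict = {}
    for line in Path(path).read_text().splitlines():
        fields = line.rstrip("\n").split("\t")
        if len(fields) >= 3 and fields[0]:
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_truth(truth: TruthBundle, path) -> None:
    payload = {
        "module_of_gene": {g: int(m) for g, m in truth.module_of_gene.items()},
        "deg_labels": truth.deg_labels.to_dict(),
        "prognostic_module": int(truth.prognostic_module),
        "hub_genes": list(truth.hub_genes),
        "methyl_changed": truth.methyl_changed.to_dict(),
        "latent_factors": {
            "index": list(truth.latent_factors.index),
            "columns": [int(c) for c in truth.latent_factors.columns],
            "data": truth.latent_factors.to_numpy().tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> TruthBundle:
    payload = json.loads(Path(path).read_text())
    lf = payload["latent_factors"]
    return TruthBundle(
        module_of_gene=pd.Series(payload["module_of_gene"]),
        deg_labels=pd.Series(payload["deg_labels"]),
        prognostic_module=payload["prognostic_module"],
        hub_genes=payload["hub_genes"],
        methyl_changed=pd.Series(payload["methyl_changed"]),
        latent_factors=pd.DataFrame(lf["data"], index=lf["index"],
                                    columns=lf["columns"]),
    )
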