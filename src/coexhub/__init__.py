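"""coexhub: gene co-expression network analysis of tumor cohorts.

A tested pipeline for the classic integrated network workflow:
differential-expression screening (fold change + t-test), thresholded
Pearson co-expression network construction, multi-algorithm module
detection with modularity selection, module-eigengene trait association
and Cox PS-value aggregation, nine-centrality hub-gene identification on a
protein-interaction network, and validation (independent-cohort tests,
ROC/AUC, methylation, over-representation) — plus a synthetic-data
generator with planted ground truth so every stage runs and can be
benchmarked without any download.
"""

from importlib import resources

import pandas as pd

from .centrality import (ALGORITHM_ORDER, HubSet, bottleneck_score,
                         build_ppi, distance_scores, epc_score,
                         merge_top_k, neighborhood_scores,
                         path_count_scores, score_table)
from .communities import (detect_edge_betweenness, detect_label_propagation,
                          detect_multilevel, modularity, select_partition)
from .containers import (ExpressionMatrix, MethylationData, Partition,
                         TruthBundle)
from .gcn import correlation_screen, extract_gcn, network_density
from .modtrait import (compute_eigengenes, cox_ps, module_eigengene,
                       select_key_module, trait_association)
from .pipeline import AnalysisResult, RunConfig, analyze, run_pipeline
from .preprocess import (detect_outlier_samples, filter_low_expression,
                         identify_degs)
from .synth import (SynthConfig, generate_all, generate_clinical,
                    generate_expression, generate_methylation, generate_ppi)
from .validate import (methylation_test, ora_hypergeometric, roc_auc,
                       validate_de)

__version__ = "0.1.0"


def load_published_score_table() -> pd.DataFrame:
    """The published nine-algorithm centrality score table for a liver
    cancer co-expression module's PPI network (16 genes x 9 columns),
    bundled as the worked example for :func:`merge_top_k`."""
    path = resources.files("coexhub").joinpath(
        "data/hcc_module_centrality_scores.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", index_col="gene")
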