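"""Synthetic tumor cohort generator with planted ground truth.

Emulates the statistical structure the co-expression pipeline assumes:

* block-correlated tumor expression — each planted module follows a
  one-factor model on the log2 scale, ``z_g = lam_g * f_b + sqrt(1 - lam_g^2) * eps``,
  so within-block Pearson correlations concentrate near ``lam^2``;
* planted differential expression (tumor mean shifted by +/- log2 fold
  change relative to normal) on all module genes plus a slice of background;
* clinical indicators (ordinal T, binary N/M/event) and exponential survival
  times driven by one designated module's latent factor;
* a hub-structured scored protein-interaction edge list over the prognostic
  module (STRING-style combined scores on the 0-1000 scale);
* paired tumor/normal methylation beta values with shifted means for
  designated genes.

Consecutive blocks are tied together by short "rotating bridges": for each
adjacent block pair, a few genes load on a mixture
``cos(theta) * f_b + sin(theta) * f_{b+1}`` with theta stepping from 0 to
pi/2, so each bridge gene correlates strongly with its neighbours in the
chain and with its home block.  Without a bridge each block would be an
isolated component and the largest-connected-component step would discard
all but one planted module; orthogonal factors cannot be linked by single
genes at a correlation threshold of 0.65 (two loadings a, b with
a^2 + b^2 <= 1 cannot both reach 0.65 / 0.98), so the gradual rotation is
the minimal construction that survives thresholding robustly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .containers import ExpressionMatrix, MethylationData, TruthBundle

__all__ = [
    "SynthConfig",
    "generate_expression",
    "generate_clinical",
    "generate_ppi",
    "generate_methylation",
    "generate_all",
]

# stage offsets for seed fan-out, so each generator draws an independent,
# individually reproducible stream from the one user-facing seed
_EXPR, _CLIN, _PPI, _METHYL = 0, 1, 2, 3

# target marginal distribution of the ordinal tumor stage T in {1..4}
_T_PROPORTIONS = (0.45, 0.30, 0.15, 0.10)


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults describe a scaled-down tumor-dominant cohort (200 tumor /
    50 normal samples, 1200 genes) with three planted co-expression blocks
    of >= 50 genes each, factor loadings in [0.85, 0.98] (within-block
    correlations ~0.72-0.96), log2 fold changes in [1, 3] on a quarter of
    the genes, and survival/stage links driven by block 0.
    """

    n_genes: int = 1200
    n_tumor: int = 200
    n_normal: int = 50
    module_sizes: tuple = (80, 60, 50)
    factor_loading_range: tuple = (0.85, 0.98)
    de_fraction: float = 0.25
    de_log2fc_range: tuple = (1.0, 3.0)
    down_fraction: float = 0.1          # share of background DEGs that are down
    noise_sd: float = 0.5               # log2-scale sd of gene expression
    low_expr_fraction: float = 0.05     # genes planted below the max-FPKM filter
    base_log2_mean: float = 3.0
    base_log2_sd: float = 1.5
    prognostic_module: int = 0
    hazard_beta: float = 1.0            # log-hazard per unit of the module factor
    baseline_hazard: float = 0.001      # events per day; mean time ~1000 d
    censor_max: float = 3000.0          # uniform censoring window, ~30% censored
    trait_link_strength: float = 1.0    # slope of the latent ordinal/logistic links
    methyl_shift: float = 0.2           # beta-scale mean shift of changed genes
    n_methyl_pairs: int = 20
    ppi_background_p: float = 0.05
    hub_attach_p: float = 0.85
    n_hubs: int = 3
    n_connectors: int = 3               # bridge genes per adjacent block pair
    connector_loading: float = 0.95     # overall loading of bridge genes
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        n_connect = self.n_connectors * max(0, len(self.module_sizes) - 1)
        if sum(self.module_sizes) + n_connect > self.n_genes:
            raise ValueError("module sizes (plus bridge genes) exceed n_genes")
        for name in ("de_fraction", "down_fraction", "low_expr_fraction",
                     "ppi_background_p", "hub_attach_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.factor_loading_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("factor_loading_range must lie inside (0, 1)")
        if not 0.0 <= self.methyl_shift < 1.0:
            raise ValueError("methyl_shift must lie in [0, 1)")
        if self.module_sizes and not (
            0 <= self.prognostic_module < len(self.module_sizes)
        ):
            raise ValueError("prognostic_module out of range")
        if self.module_sizes and self.n_hubs > self.module_sizes[self.prognostic_module]:
            raise ValueError("n_hubs exceeds the prognostic module size")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


def _gene_ids(n: int) -> list:
    return [f"G{i:05d}" for i in range(n)]


def generate_expression(config: SynthConfig) -> tuple[ExpressionMatrix, TruthBundle]:
    """Draw the labelled expression matrix and its planted truth.

    Returns the FPKM-scale matrix (tumor columns first) and a
    :class:`TruthBundle` carrying block membership, DEG labels, hub
    identities, methylation-change labels and the tumor latent factors.
    """
    rng = config.rng(_EXPR)
    genes = _gene_ids(config.n_genes)
    tumor = [f"T{i:04d}" for i in range(config.n_tumor)]
    normal = [f"N{i:04d}" for i in range(config.n_normal)]

    n_blocks = len(config.module_sizes)
    module_of_gene = pd.Series(-1, index=pd.Index(genes, name="gene"))

    # loading matrix over (structured genes) x (block factors)
    rows: list[tuple[str, np.ndarray]] = []
    pos = 0
    lo, hi = config.factor_loading_range
    for b, size in enumerate(config.module_sizes):
        for _ in range(size):
            g = genes[pos]
            pos += 1
            load = np.zeros(n_blocks)
            load[b] = rng.uniform(lo, hi)
            module_of_gene[g] = b
            rows.append((g, load))
    for b in range(n_blocks - 1):
        for j in range(config.n_connectors):
            g = genes[pos]
            pos += 1
            theta = (j + 1) * np.pi / (2 * (config.n_connectors + 1))
            load = np.zeros(n_blocks)
            load[b] = config.connector_loading * np.cos(theta)
            load[b + 1] = config.connector_loading * np.sin(theta)
            module_of_gene[g] = b if theta <= np.pi / 4 else b + 1
            rows.append((g, load))
    structured = [g for g, _ in rows]
    L = np.array([l for _, l in rows]) if rows else np.zeros((0, n_blocks))

    # DEG labels: module/connector genes first (all up), background fills
    deg_labels = pd.Series("none", index=module_of_gene.index)
    n_de = int(round(config.de_fraction * config.n_genes))
    de_genes = structured[:n_de]
    background = [g for g in genes if module_of_gene[g] == -1]
    n_extra = n_de - len(de_genes)
    extra: list = []
    if n_extra > 0:
        extra = list(rng.choice(background, size=min(n_extra, len(background)),
                                replace=False))
        de_genes = de_genes + extra
    deg_labels[de_genes] = "up"
    n_down = int(round(config.down_fraction * len(extra)))
    if n_down:
        deg_labels[extra[:n_down]] = "down"

    # baseline log2 means; a slice of unstructured, non-DE genes sits far
    # below the max-FPKM filter threshold to exercise the filtering stage
    mu = rng.normal(config.base_log2_mean, config.base_log2_sd, config.n_genes)
    non_de_bg = [g for g in background if deg_labels[g] == "none"]
    n_low = int(round(config.low_expr_fraction * config.n_genes))
    low_genes = non_de_bg[: min(n_low, len(non_de_bg))]
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in low_genes:
        mu[gene_pos[g]] = -5.0

    # planted log2 fold changes (tumor mean minus normal mean); hub genes
    # draw from the upper half of the range — a hub is by definition a
    # member of the DEG-derived module, so its differential expression
    # must sit clearly inside the callable region, mirroring the strong
    # tumor up-regulation reported for real hub genes
    hubs = ([g for g in genes if module_of_gene[g] == config.prognostic_module]
            [: config.n_hubs] if n_blocks else [])
    fc_lo, fc_hi = config.de_log2fc_range
    fc_mid = 0.5 * (fc_lo + fc_hi)
    delta = np.zeros(config.n_genes)
    for g in de_genes:
        mag = rng.uniform(fc_mid if g in hubs else fc_lo, fc_hi)
        delta[gene_pos[g]] = -mag if deg_labels[g] == "down" else mag

    # tumor draws: one-factor model for structured genes, iid for the rest
    F = rng.normal(size=(config.n_tumor, n_blocks))
    z_tumor = rng.normal(size=(config.n_genes, config.n_tumor))
    if structured:
        resid = np.sqrt(np.clip(1.0 - (L**2).sum(axis=1), 0.0, None))
        idx = np.array([gene_pos[g] for g in structured])
        z_tumor[idx] = (L @ F.T) + resid[:, None] * z_tumor[idx]
    z_normal = rng.normal(size=(config.n_genes, config.n_normal))

    log2_tumor = mu[:, None] + delta[:, None] + config.noise_sd * z_tumor
    log2_normal = mu[:, None] + config.noise_sd * z_normal
    values = pd.DataFrame(
        np.exp2(np.concatenate([log2_tumor, log2_normal], axis=1)),
        index=pd.Index(genes, name="gene"),
        columns=tumor + normal,
    )
    groups = pd.Series(["tumor"] * len(tumor) + ["normal"] * len(normal),
                       index=values.columns, name="group")

    methyl_changed = pd.Series("none", index=module_of_gene.index)
    methyl_changed[hubs] = "hypo"
    hyper_pool = [g for g in non_de_bg if g not in low_genes]
    hyper = list(rng.choice(hyper_pool, size=min(len(hubs), len(hyper_pool)),
                            replace=False))
    methyl_changed[hyper] = "hyper"

    truth = TruthBundle(
        module_of_gene=module_of_gene,
        deg_labels=deg_labels,
        prognostic_module=config.prognostic_module,
        hub_genes=hubs,
        methyl_changed=methyl_changed,
        latent_factors=pd.DataFrame(F, index=tumor,
                                    columns=list(range(n_blocks))),
        loadings=pd.DataFrame(L, index=pd.Index(structured, name="gene"),
                              columns=list(range(n_blocks))),
    )
    return ExpressionMatrix(values, groups), truth


def generate_clinical(truth: TruthBundle, expr: ExpressionMatrix,
                      config: SynthConfig) -> pd.DataFrame:
    """Clinical table for the tumor samples.

    Ordinal T (1-4), binary N/M/event follow latent-threshold / logistic
    links on the prognostic module's factor with slope
    ``trait_link_strength`` (T strongest, then event, N, M).  Survival time
    is exponential with hazard ``baseline_hazard * exp(hazard_beta * f)``,
    censored by an independent uniform over [0, censor_max].
    """
    tumor = list(expr.tumor_samples)
    if not tumor:
        raise ValueError("no tumor samples in the expression matrix")
    rng = config.rng(_CLIN)
    f = truth.latent_factors.loc[tumor, truth.prognostic_module].to_numpy()
    s = config.trait_link_strength

    latent = s * f + rng.normal(size=len(tumor))
    cuts = norm.ppf(np.cumsum(_T_PROPORTIONS[:-1]),
                    scale=np.sqrt(1.0 + s**2))
    T = 1 + np.digitize(latent, cuts)
    N = rng.binomial(1, expit(-0.85 + 0.4 * s * f))
    M = rng.binomial(1, expit(-2.2 + 0.2 * s * f))
    event = rng.binomial(1, expit(-0.6 + 0.7 * s * f))

    hazard = config.baseline_hazard * np.exp(config.hazard_beta * f)
    t_true = rng.exponential(1.0 / hazard)
    censor = rng.uniform(0.0, config.censor_max, size=len(tumor))
    time = np.minimum(t_true, censor)
    status = (t_true <= censor).astype(int)
    time = np.maximum(time, 1e-8)  # guard exact zeros

    return pd.DataFrame(
        {"time": time, "status": status, "event": event, "T": T, "N": N, "M": M},
        index=pd.Index(tumor, name="sample_id"),
    )


def generate_ppi(truth: TruthBundle, config: SynthConfig) -> pd.DataFrame:
    """Scored protein-interaction edge list over the prognostic module.

    Hub genes attach to each other module member with probability
    ``hub_attach_p`` and carry high combined scores (600-999); background
    edges are Erdos-Renyi with ``ppi_background_p`` and scores 150-699.
    Returns a STRING-export-style frame (protein1, protein2, combined_score
    on the 0-1000 scale), undirected and simple.
    """
    members = truth.module_genes(truth.prognostic_module)
    if not members:
        raise ValueError("prognostic module has no genes")
    if config.n_hubs > len(members):
        raise ValueError("n_hubs exceeds the module size")
    rng = config.rng(_PPI)
    hubs = set(truth.hub_genes)
    scores: dict[tuple, int] = {}
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            key = (a, b) if a < b else (b, a)
            if (a in hubs or b in hubs) and rng.random() < config.hub_attach_p:
                scores[key] = int(rng.integers(600, 1000))
            elif rng.random() < config.ppi_background_p:
                s = int(rng.integers(150, 700))
                scores[key] = max(s, scores.get(key, 0))
    records = [(a, b, s) for (a, b), s in sorted(scores.items())]
    return pd.DataFrame(records, columns=["protein1", "protein2", "combined_score"])


def generate_methylation(truth: TruthBundle,
                         config: SynthConfig) -> MethylationData:
    """Paired tumor/normal methylation beta values.

    Per gene, betas centre on a baseline in (0.35, 0.65) with a shared
    per-patient effect inducing pairing correlation; genes labelled hypo
    (hyper) have the tumor mean shifted down (up) by ``methyl_shift``.
    Values falling outside (0, 1) are clipped with a warning.
    """
    rng = config.rng(_METHYL)
    genes = list(truth.module_of_gene.index)
    n_pairs = config.n_methyl_pairs
    base = rng.uniform(0.35, 0.65, size=len(genes))
    shift = truth.methyl_changed.map(
        {"hypo": -config.methyl_shift, "hyper": config.methyl_shift, "none": 0.0}
    ).to_numpy()

    patient = rng.normal(0.0, 0.05, size=(len(genes), n_pairs))
    tum = (base[:, None] + shift[:, None] + patient
           + rng.normal(0.0, 0.05, size=(len(genes), n_pairs)))
    nor = base[:, None] + patient + rng.normal(0.0, 0.05, size=(len(genes), n_pairs))

    eps = 1e-3
    n_clip = int((tum <= 0).sum() + (tum >= 1).sum()
                 + (nor <= 0).sum() + (nor >= 1).sum())
    if n_clip:
        warnings.warn(f"{n_clip} beta values clipped into (0, 1)")
    tum = np.clip(tum, eps, 1 - eps)
    nor = np.clip(nor, eps, 1 - eps)

    t_ids = [f"P{i:02d}_T" for i in range(n_pairs)]
    n_ids = [f"P{i:02d}_N" for i in range(n_pairs)]
    values = pd.DataFrame(np.concatenate([tum, nor], axis=1),
                          index=pd.Index(genes, name="gene"),
                          columns=t_ids + n_ids)
    pairing = pd.DataFrame({
        "pair_id": [f"P{i:02d}" for i in range(n_pairs)],
        "tumor_sample": t_ids,
        "normal_sample": n_ids,
    })
    return MethylationData(values, pairing)


def generate_all(config: SynthConfig):
    """Convenience: all four data sets plus truth, from one config."""
    expr, truth = generate_expression(config)
    clinical = generate_clinical(truth, expr, config)
    ppi = generate_ppi(truth, config)
    methylation = generate_methylation(truth, config)
    return expr, clinical, ppi, methylation, truth
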