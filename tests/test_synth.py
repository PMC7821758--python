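"""Generator contracts: determinism, calibration, and planted structure."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import coexhub as cx
from coexhub.synth import SynthConfig


def test_seed_determinism_across_all_generators():
    """Identical config + seed must give byte-identical outputs."""
    cfg = SynthConfig(n_genes=300, n_tumor=50, n_normal=20,
                      module_sizes=(60,), seed=11)
    a = cx.generate_all(cfg)
    b = cx.generate_all(cfg)
    pd.testing.assert_frame_equal(a[0].values, b[0].values)
    pd.testing.assert_frame_equal(a[1], b[1])       # clinical
    pd.testing.assert_frame_equal(a[2], b[2])       # ppi
    pd.testing.assert_frame_equal(a[3].values, b[3].values)
    pd.testing.assert_series_equal(a[4].deg_labels, b[4].deg_labels)


def test_within_block_correlation_tracks_squared_loading():
    """With loading 0.9 fixed, mean within-block FPKM correlation ~ 0.81."""
    cfg = SynthConfig(n_genes=60, n_tumor=200, n_normal=10,
                      module_sizes=(60,), factor_loading_range=(0.9, 0.9),
                      de_fraction=0.0, low_expr_fraction=0.0, seed=5)
    expr, truth = cx.generate_expression(cfg)
    X = expr.tumor_values.loc[truth.module_genes(0)].to_numpy()
    C = np.corrcoef(X)
    off = C[np.triu_indices_from(C, k=1)]
    assert 0.78 <= off.mean() <= 0.84


def test_no_planted_effects_means_calibrated_t_tests():
    """de_fraction=0: a stringent t-test rejects at most 0.5% of genes."""
    n_reject = n_total = 0
    for seed in range(10):
        cfg = SynthConfig(n_genes=300, n_tumor=100, n_normal=50,
                          module_sizes=(), de_fraction=0.0,
                          low_expr_fraction=0.0, seed=seed)
        expr, _ = cx.generate_expression(cfg)
        table = cx.identify_degs(expr, alpha=1.0)  # keep raw p-values
        n_reject += int((table["p_value"] < 1e-3).sum())
        n_total += len(table)
    assert n_reject / n_total <= 0.005


def test_clinical_contracts_and_null_trait_link():
    cfg = SynthConfig(n_genes=80, n_tumor=2000, n_normal=10,
                      module_sizes=(60,), trait_link_strength=0.0, seed=2)
    expr, truth = cx.generate_expression(cfg)
    clin = cx.generate_clinical(truth, expr, cfg)
    assert set(clin["event"].unique()) <= {0, 1}
    assert (clin["time"] > 0).all()
    assert clin["T"].between(1, 4).all()
    f = truth.latent_factors[0]
    r = np.corrcoef(f, clin.loc[f.index, "T"])[0, 1]
    assert abs(r) <= 0.05


def test_survival_times_recover_planted_hazard():
    """Cox on the planted factor recovers hazard_beta=1 (10-seed median)."""
    coefs = []
    for seed in range(10):
        cfg = SynthConfig(n_genes=80, n_tumor=500, n_normal=10,
                          module_sizes=(60,), hazard_beta=1.0, seed=seed)
        expr, truth = cx.generate_expression(cfg)
        clin = cx.generate_clinical(truth, expr, cfg)
        df = pd.DataFrame({"time": clin["time"], "status": clin["status"],
                           "f": truth.latent_factors[0]})
        fit = CoxPHFitter().fit(df, "time", "status")
        coefs.append(fit.params_["f"])
    assert 0.8 <= float(np.median(coefs)) <= 1.2


def test_ppi_star_construction_and_score_range():
    cfg = SynthConfig(n_genes=60, n_tumor=50, n_normal=10,
                      module_sizes=(60,), n_hubs=1, hub_attach_p=1.0,
                      ppi_background_p=0.0, seed=3)
    _, truth = cx.generate_expression(cfg)
    edges = cx.generate_ppi(truth, cfg)
    assert edges["combined_score"].between(0, 1000).all()
    G = cx.build_ppi(edges, min_score=0.0)
    hub = truth.hub_genes[0]
    assert G.degree(hub) == 59
    assert all(G.degree(v) >= 1 for v in G.nodes)


def test_planted_hubs_lead_module_degree_ranking():
    """With defaults, planted hubs occupy top-5 degree in >= 9/10 seeds."""
    wins = 0
    for seed in range(10):
        cfg = SynthConfig(seed=seed)
        _, truth = cx.generate_expression(cfg)
        edges = cx.generate_ppi(truth, cfg)
        G = cx.build_ppi(edges)
        deg = pd.Series(dict(G.degree()))
        top5 = set(deg.nlargest(5).index)
        wins += set(truth.hub_genes) <= top5
    assert wins >= 9


def test_hub_count_cannot_exceed_module_size():
    with pytest.raises(ValueError):
        SynthConfig(n_genes=200, module_sizes=(50,), n_hubs=51)


def test_module_sizes_cannot_exceed_gene_count():
    with pytest.raises(ValueError):
        SynthConfig(n_genes=100, module_sizes=(80, 60))


def test_methylation_scale_null_calibration_and_power():
    # beta-scale contract + null rejection rate over 10 seeds
    reject = total = 0
    power_hits = 0
    for seed in range(10):
        null_cfg = SynthConfig(n_genes=200, module_sizes=(60,),
                               methyl_shift=0.0, seed=seed)
        _, truth = cx.generate_expression(null_cfg)
        M = cx.generate_methylation(truth, null_cfg)
        assert ((M.values.to_numpy() > 0) & (M.values.to_numpy() < 1)).all()
        res = cx.methylation_test(M)
        unchanged = truth.methyl_changed[truth.methyl_changed == "none"].index
        reject += int((res.loc[unchanged, "p_value"] < 0.05).sum())
        total += len(unchanged)

        shift_cfg = SynthConfig(n_genes=200, module_sizes=(60,),
                                methyl_shift=0.2, seed=seed)
        _, truth2 = cx.generate_expression(shift_cfg)
        M2 = cx.generate_methylation(truth2, shift_cfg)
        res2 = cx.methylation_test(M2)
        hypo = truth2.methyl_changed[truth2.methyl_changed == "hypo"].index[0]
        power_hits += res2.loc[hypo, "call"] == "hypomethylation"
    se = np.sqrt(0.05 * 0.95 / total)
    assert reject / total <= 0.05 + 3 * se
    assert power_hits >= 9
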