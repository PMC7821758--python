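"""Low-expression filter, outlier clustering, and the FC-t DEG rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coexhub as cx
from coexhub.containers import ExpressionMatrix
from coexhub.synth import SynthConfig


def _matrix(data, groups):
    values = pd.DataFrame(data).T
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    values.index = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(values, pd.Series(groups, index=values.columns))


def test_filter_keeps_boundary_and_is_idempotent():
    X = _matrix(
        {0: [0.9, 0.9, 0.9, 0.9],        # below threshold everywhere -> out
         1: [1.0, 0.0, 0.0, 0.0],        # one tumor value at 1.0 -> kept
         2: [0.2, 0.3, 5.0, 0.1]},       # high in normal only -> kept
        ["tumor", "tumor", "normal", "normal"])
    f1 = cx.filter_low_expression(X)
    assert list(f1.gene_ids) == ["g1", "g2"]
    f2 = cx.filter_low_expression(f1)
    pd.testing.assert_frame_equal(f1.values, f2.values)


def test_identical_samples_yield_no_outliers():
    values = pd.DataFrame(np.ones((10, 6)),
                          index=[f"g{i}" for i in range(10)],
                          columns=[f"s{i}" for i in range(6)])
    X = ExpressionMatrix(values, pd.Series("tumor", index=values.columns))
    assert cx.detect_outlier_samples(X) == []


def test_single_shifted_sample_is_flagged():
    rng = np.random.default_rng(0)
    values = pd.DataFrame(rng.uniform(1, 2, size=(50, 30)),
                          index=[f"g{i}" for i in range(50)],
                          columns=[f"s{i}" for i in range(30)])
    values["s7"] += 100.0
    X = ExpressionMatrix(values, pd.Series("tumor", index=values.columns))
    assert cx.detect_outlier_samples(X) == ["s7"]


def test_deg_welch_oracle_and_boundary():
    """Frozen Welch oracle: t=7/sqrt(5/3), df by Welch-Satterthwaite."""
    X = _matrix({0: [8, 10, 12, 2, 3, 4]},
                ["tumor"] * 3 + ["normal"] * 3)
    table = cx.identify_degs(X)
    # independent oracle: explicit Welch statistic and t CDF
    se2 = 4 / 3 + 1 / 3
    t = (10 - 3) / np.sqrt(se2)
    df = se2**2 / ((4 / 3)**2 / 2 + (1 / 3)**2 / 2)
    p = 2 * stats.t.sf(t, df)
    assert table.loc["g0", "fold_change"] == pytest.approx(10 / 3)
    assert table.loc["g0", "p_value"] == pytest.approx(p, rel=1e-10)
    assert table.loc["g0", "direction"] == "up"


def test_fold_change_two_exactly_is_up():
    """Inclusive boundary: FC = 2.0 with small p is called up."""
    tumor = [10.0, 10.01, 9.99, 10.0]
    normal = [v / 2 for v in tumor]
    X = _matrix({0: tumor + normal}, ["tumor"] * 4 + ["normal"] * 4)
    table = cx.identify_degs(X)
    assert table.loc["g0", "fold_change"] == pytest.approx(2.0, abs=1e-12)
    assert table.loc["g0", "direction"] == "up"


def test_identical_groups_are_not_degs():
    X = _matrix({0: [5, 6, 7, 5, 6, 7]}, ["tumor"] * 3 + ["normal"] * 3)
    table = cx.identify_degs(X)
    assert table.loc["g0", "fold_change"] == pytest.approx(1.0)
    assert table.loc["g0", "direction"] == "none"


def test_deg_calls_monotone_in_thresholds():
    rng = np.random.default_rng(4)
    values = pd.DataFrame(rng.lognormal(1, 1, size=(100, 20)),
                          index=[f"g{i}" for i in range(100)],
                          columns=[f"s{i}" for i in range(20)])
    X = ExpressionMatrix(values, pd.Series(["tumor"] * 12 + ["normal"] * 8,
                                           index=values.columns))
    base = (cx.identify_degs(X, alpha=0.05)["direction"] == "up").sum()
    looser_alpha = (cx.identify_degs(X, alpha=0.2)["direction"] == "up").sum()
    looser_fc = (cx.identify_degs(X, fc_up=1.5)["direction"] == "up").sum()
    assert looser_alpha >= base
    assert looser_fc >= base


def test_deg_recovery_on_planted_fold_changes():
    """log2FC=2 at 50/50 samples: sensitivity >= 0.95, FDR <= 0.10."""
    sens, fdr = [], []
    for seed in range(10):
        cfg = SynthConfig(n_genes=400, n_tumor=50, n_normal=50,
                          module_sizes=(60,), de_log2fc_range=(2.0, 2.0),
                          noise_sd=0.5, seed=seed)
        expr, truth = cx.generate_expression(cfg)
        table = cx.identify_degs(cx.filter_low_expression(expr))
        called = table.index[table["direction"] != "none"]
        truth_de = set(truth.deg_labels.index[truth.deg_labels != "none"])
        hits = sum(1 for g in called if g in truth_de)
        sens.append(hits / len(truth_de))
        fdr.append((len(called) - hits) / len(called) if len(called) else 0.0)
    assert np.median(sens) >= 0.95
    assert np.median(fdr) <= 0.10
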