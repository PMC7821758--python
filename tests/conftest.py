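import pytest

import coexhub as cx


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default study conditions."""
    cfg = cx.SynthConfig(seed=1)
    expr, clinical, ppi, methylation, truth = cx.generate_all(cfg)
    return dict(config=cfg, expr=expr, clinical=clinical, ppi=ppi,
                methylation=methylation, truth=truth)


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Full pipeline result on the default cohort (shared across tests)."""
    return cx.analyze(default_cohort["expr"], default_cohort["clinical"],
                      default_cohort["ppi"], cx.RunConfig(seed=1),
                      methylation=default_cohort["methylation"])


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced two-block cohort for fast pipeline-level tests."""
    cfg = cx.SynthConfig(n_genes=600, n_tumor=120, n_normal=40,
                         module_sizes=(55, 50), seed=7)
    expr, clinical, ppi, methylation, truth = cx.generate_all(cfg)
    return dict(config=cfg, expr=expr, clinical=clinical, ppi=ppi,
                methylation=methylation, truth=truth)
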