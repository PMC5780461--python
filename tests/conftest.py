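import logging

import pytest

from cnvx.cn_genotype import assign_cn_states
from cnvx.expr_assoc import compute_norm_factors, fit_dispersion
from cnvx.simdata import default_config, simulate_cohort

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def sim():
    """Default synthetic cohort at reduced gene count, shared across tests."""
    cfg = default_config(seed=3, n_genes=300)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def geno_matrix(sim):
    cfg, res = sim
    snp = res.calls[res.calls["source"] == "snp"]
    return assign_cn_states(snp, res.regions, res.cohort.offspring)


@pytest.fixture(scope="session")
def cm_norm(sim):
    _, res = sim
    return compute_norm_factors(res.counts)


@pytest.fixture(scope="session")
def dispersion(cm_norm):
    return fit_dispersion(cm_norm)
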