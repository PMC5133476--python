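import numpy as np
import pytest

from r2vim import (ForestParams, SimConfig, simulate_genotypes,
                   simulate_phenotype, truth_annotation, with_functional)
from r2vim.core import make_forest_inputs, run_r2vim
from r2vim.linreg import scan


@pytest.fixture(scope="session")
def signal_dataset():
    """Small dataset with two functional variants of different strengths."""
    cfg = SimConfig(n_samples=250, n_variants=60, maf_range=(0.1, 0.5),
                    noise_sd=1.0, seed=42,
                    covariate_effects={"sex": 1.0, "age": 0.05})
    cfg = with_functional(cfg, {4: 1.2, 30: 0.6})
    gm = simulate_genotypes(cfg)
    ph = simulate_phenotype(gm, cfg)
    truth = truth_annotation(cfg, gm)
    return cfg, gm, ph, truth


@pytest.fixture(scope="session")
def signal_ris(signal_dataset):
    """A 5-run RIS matrix on the signal dataset (shared across tests)."""
    _, gm, ph, _ = signal_dataset
    X, y, ids, mask = make_forest_inputs(gm, ph)
    return run_r2vim(X, y, params=ForestParams(ntree=150), n_runs=5,
                     base_seed=7, variable_ids=ids, variant_mask=mask)


@pytest.fixture(scope="session")
def signal_scan(signal_dataset):
    _, gm, ph, _ = signal_dataset
    return scan(gm, ph, ["sex", "medication", "smoking", "age"])


@pytest.fixture()
def noise_xy():
    rng = np.random.default_rng(314)
    return rng.standard_normal((120, 15)), rng.standard_normal(120)
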