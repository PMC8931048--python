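import warnings

import numpy as np
import pytest

from epistate.pipeline import run_pipeline
from epistate.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """Full-scale default simulation (seed 1), shared across the session."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_study):
    """Pipeline run on the default study, without the slow state-model fit
    (the HMM stage has its own dedicated recovery tests)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(default_study, seed=1, fit_states=False)


@pytest.fixture(scope="session")
def small_study():
    """Tiny study for fast structural checks."""
    cfg = SimulationConfig(
        seed=7, n_chrom=1, chrom_length=2_000_000, n_genes=60,
        n_samples_per_genotype=3, n_up_genes=15, n_down_genes=5,
        n_planted_enhancers=10, cells_per_sample=50, n_features_sc=40,
        sc_wt_n_archetypes=5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
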