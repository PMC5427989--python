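import warnings

import numpy as np
import pytest

import twinewas as tw

# liability fits on deliberately small cohorts warn about pair counts;
# keep test output clean without hiding real failures
warnings.filterwarnings("ignore", message="fewer than 20 complete pairs")
warnings.filterwarnings("ignore", message="only .* complete cases")


@pytest.fixture(scope="session")
def small_sim():
    """Default-structure cohort at desk scale: 1708 individuals, 400 bins."""
    cfg = tw.SimConfig(n_bins=400, seed=3)
    matrix, cohort, truth = tw.simulate_cohort(cfg)
    return cfg, matrix, cohort, truth


@pytest.fixture(scope="session")
def clean_twin_sim():
    """Large balanced twin set with known ACE shares and no zero inflation,
    for correlation-structure checks (bin_h2=0.4, bin_c2=0.1, R_repeat=0.7)."""
    cfg = tw.SimConfig(
        n_mz_pairs=2000, n_dz_pairs=2000, n_singletons=0, n_bins=120,
        frac_stable_bins=1.0, bin_h2=0.4, bin_c2=0.1, test_retest_r=0.7,
        zero_inflation=0.0, causal_bin_effects=(), repeat_fraction=0.25,
        seed=11,
    )
    matrix, cohort, truth = tw.simulate_cohort(cfg)
    return cfg, matrix, cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
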