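import warnings

import numpy as np
import pytest

from igeprs import SimConfig, simulate_reference_panel, simulate_phenotypes

warnings.filterwarnings("ignore", message="score_prs")


@pytest.fixture(scope="session")
def panel500():
    """500 controls x 1,000 SNPs with moderate heritability, plus phenotypes."""
    cfg = SimConfig(n_controls=500, n_cases=0, n_snps=1000, n_blocks=50,
                    h2=0.3, n_causal=25, seed=7)
    geno, truth = simulate_reference_panel(cfg)
    cohort = simulate_phenotypes(geno, truth, cfg)
    return cfg, geno, truth, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
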