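import numpy as np
import pytest

from ppigat.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests."""
    cfg = SyntheticConfig(
        n_genes=120,
        module_sizes=(30, 30, 30),
        within_module_cor=0.8,
        signal_genes=3,
        effect_size_d=1.5,
        feature_target_aucs=(0.8, 0.8, 0.8),
        seed=11,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
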