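import numpy as np
import pytest

from phenowatch.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact three-group cohort with all streams, plus its ground truth."""
    cfg = SimConfig(n_per_group={"CN": 12, "SCD": 6, "CI": 6}, seed=42,
                    duration_days=(7, 14))
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
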