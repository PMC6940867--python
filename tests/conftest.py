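import numpy as np
import pytest

import wearcal as wc


@pytest.fixture(scope="session")
def cad_protocol():
    return wc.build_standard_protocol("CAD")


@pytest.fixture(scope="session")
def hf_protocol():
    return wc.build_standard_protocol("HFrEF")


@pytest.fixture(scope="session")
def small_records():
    """Four simulated patients (2 per group) with default noise settings."""
    return wc.simulate_study(wc.SimulationConfig(n_per_group=2, seed=7))


@pytest.fixture(scope="session")
def noise_free_record():
    """One noise-free, outlier-free, gap-free CAD patient."""
    cfg = wc.SimulationConfig(
        n_per_group=1, seed=11, noise_cv=0.0, outlier_rate=0.0, rest_gap_range_s=(0.0, 0.0)
    )
    return wc.simulate_study(cfg)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
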