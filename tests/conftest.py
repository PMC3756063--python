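import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small simulated cohort shared by io/report/acceptance tests."""
    from revfiber.simulate import SimConfig, generate_cohort

    config = SimConfig(n_fibers=120)
    return generate_cohort(
        config, n_mice=2, muscles=("TA", "D", "H"), master_seed=424242
    )
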