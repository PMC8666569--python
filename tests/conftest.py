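import numpy as np
import pytest

import hebbrsa as h


@pytest.fixture(scope="session")
def pool():
    return h.build_tone_pool()


@pytest.fixture(scope="session")
def design_full():
    """Default 8-run x 18-trial session."""
    return h.build_design(rng_seed=11)


@pytest.fixture(scope="session")
def design_small():
    """Smallest balanced session (2 runs) for pipeline tests."""
    return h.build_design(n_runs=2, trials_per_run=18, rng_seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
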