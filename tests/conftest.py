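import numpy as np
import pytest

import avloc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_run():
    """One calibrated full-scale pipeline run, shared across tests."""
    return avloc.run_pipeline(
        avloc.PipelineConfig(generator=avloc.default_config(seed=7))
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A light dataset (2 subjects x 6 reps) for IO and subset tests."""
    return avloc.simulate_dataset(
        avloc.default_config(seed=11, n_subjects=2, n_reps=6)
    )
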