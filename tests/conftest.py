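import numpy as np
import pytest

from veinseg import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sample():
    """One deterministic noise-free synthetic sample at the default geometry."""
    return synthetic.gen_sample(synthetic.SynthConfig(seed=7))


@pytest.fixture(scope="session")
def tiny_sample():
    """A reduced-size sample for stages that loop per pixel."""
    cfg = synthetic.SynthConfig(height=64, width=96, n_seeds=2, seed=3)
    return synthetic.gen_sample(cfg)
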