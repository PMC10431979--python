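import numpy as np
import pytest

from perfquant import PhantomSpec, synthesize_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default noiseless phantom: one CBF 60 / CBV 4 (MTT 4 s) compartment."""
    spec = PhantomSpec(noise_sigma=0.0)
    series, truth = synthesize_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def small_series():
    """Tiny deterministic DSCSeries for unit tests that don't need physics."""
    from perfquant import DSCSeries

    rng = np.random.default_rng(7)
    signal = rng.uniform(500.0, 1500.0, size=(1, 12, 8, 8)).astype(np.float32)
    return DSCSeries(signal=signal, te_s=0.0062, tr_s=1.0)
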