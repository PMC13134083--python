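import numpy as np
import pytest

from ddclock.simulate_droplets import AssaySimConfig, CpGSimConfig


@pytest.fixture
def single_channel_config():
    """One-channel well at limiting dilution (QC-pass regime)."""

    def make(seed: int, true_beta: float = 0.3, total_molecules: int = 1500, **kw):
        return AssaySimConfig(
            seed=seed,
            cpgs={"FHL2": CpGSimConfig(true_beta=true_beta, total_molecules=total_molecules)},
            **kw,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
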