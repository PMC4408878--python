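import numpy as np
import pytest

from pyloric import synth


@pytest.fixture(scope="session")
def noiseless_truth():
    """1.0 Hz, no jitter/drift/events: 100 exact 1-s cycles over 100 s."""
    p = synth.PreparationParams(
        prep_id="noiseless", baseline_freq=1.0, cycle_jitter_cv=0.0
    )
    return synth.generate_cycle_series(p, 100.0, rng_seed=0)


@pytest.fixture(scope="session")
def jittered_truth():
    """1000+ cycles at 1.0 Hz with 5% period jitter, default phase targets."""
    p = synth.PreparationParams(
        prep_id="jittered", baseline_freq=1.0, cycle_jitter_cv=0.05
    )
    return synth.generate_cycle_series(p, 1100.0, rng_seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
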