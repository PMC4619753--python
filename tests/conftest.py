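import numpy as np
import pytest

from nirsfc import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_probe():
    return synthetic.make_probe(2)  # 2 pairs -> 4 measurement rows


@pytest.fixture
def small_spec():
    """A fast two-block design used across modules."""
    return synthetic.SyntheticSpec(
        n_channels=10, n_subjects=3, duration_s=120.0, sampling_rate=25.0,
        n_blocks=2, within_r=0.8, between_r=0.0, seed=11,
    )


@pytest.fixture
def small_recording(small_spec):
    rec, _ = synthetic.simulate_subject(small_spec, seed=31, subject_id="sub-01")
    return rec
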