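import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_beatset():
    """Small, mildly noisy 2-lead set for fast end-to-end tests."""
    from ccanet_ecg import SynthConfig, synth_beats
    cfg = SynthConfig(n_classes=2, beats_per_class=20, n_leads=2,
                      beat_length=64, noise_sd=0.02, baseline_amp=0.05,
                      seed=7)
    return synth_beats(cfg)


@pytest.fixture
def tiny_matrices(tiny_beatset):
    from ccanet_ecg.preprocess import normalize_beats
    bs = tiny_beatset
    return normalize_beats(bs.beats).reshape(bs.n_leads, bs.n_beats, 8, 8)
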