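import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_scene():
    """A small 8-channel scene shared by slow-ish denoising tests."""
    from eegfuse.synthetic import SceneConfig, generate_recording

    cfg = SceneConfig(seed=42, n_channels=8, duration_s=20.0)
    clean, noisy, meta = generate_recording(cfg)
    return cfg, clean, noisy, meta
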