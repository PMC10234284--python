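import numpy as np
import pytest

from dfoct.phantom import generate_phantom_pair, healthy_config, tumoral_config


@pytest.fixture(scope="session")
def small_healthy_pair():
    """Small healthy phantom (120 px, 128 frames) shared across tests."""
    cfg = healthy_config(roi_size_px=120, seed=11)
    return generate_phantom_pair(cfg, n_frames=128), cfg


@pytest.fixture(scope="session")
def small_tumoral_pair():
    cfg = tumoral_config(roi_size_px=120, seed=12)
    return generate_phantom_pair(cfg, n_frames=128), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
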