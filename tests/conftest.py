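import numpy as np
import pytest

from cyclemap.model import ManifoldModel
from cyclemap.synthetic import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained network for shape/contract tests (16x16 patches)."""
    return ManifoldModel(patch_size=16, latent_dim=4, enc_channels=(4, 8, 16),
                         disc_channels=(4, 8, 16, 32), dense=32, seed=5)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three short synthetic trajectories with ground truth (16x16)."""
    cfg = SyntheticConfig(patch_size=16, n_frames=24, period_frames=16, seed=3)
    return cfg, simulate_dataset(cfg, 3)
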