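import numpy as np
import pytest

from synfuse.encoder import EncoderConfig
from synfuse.fusion import FusionConfig
from synfuse.model import TrainConfig
from synfuse.synth import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_encoder_config() -> EncoderConfig:
    return EncoderConfig(n_layers=1, n_heads=2, d_model=16, d_ff=32, max_len=64)


@pytest.fixture(scope="session")
def tiny_fusion_config() -> FusionConfig:
    return FusionConfig(d=8, n_heads=2, highway_layers=2)


@pytest.fixture(scope="session")
def small_dataset():
    """~150 records over 10 drugs x 6 cell lines with the planted rule."""
    cfg = SyntheticConfig(n_drugs=10, n_cell_lines=6, n_genes=20,
                          n_records=150, seed=5)
    records, expr, truth = generate_dataset(cfg)
    return records, expr, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
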