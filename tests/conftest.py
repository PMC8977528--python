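import numpy as np
import pytest

from salpinx.simulate import StromaModel, render_stromal_tile


@pytest.fixture(scope="session")
def small_stroma_model() -> StromaModel:
    """64-px tile renderer: full pipeline behavior at desk scale."""
    return StromaModel(tile_size=64)


@pytest.fixture(scope="session")
def benign_tile(small_stroma_model):
    return render_stromal_tile(small_stroma_model, "Benign", seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
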