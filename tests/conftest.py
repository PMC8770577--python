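import numpy as np
import pytest

from sortcyte import SyntheticConfig, render_frame


@pytest.fixture(scope="session")
def config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def flat_background(config) -> np.ndarray:
    """Objectless frame (background + static noise + walls) as float."""
    frame, _ = render_frame(config, [])
    return frame.astype(float)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
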