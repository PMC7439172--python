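import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coins_pair():
    """Clean coin-like image with its ground truth (session-cached)."""
    from otsu2d import coins_scene, render

    return render(coins_scene(0))


@pytest.fixture(scope="session")
def uneven_pair():
    """Contrast-inversion image with its ground truth (session-cached)."""
    from otsu2d import render, uneven_scene

    return render(uneven_scene(0))
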