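import numpy as np
import pytest

from crownscope.synthetic import gen_scene


@pytest.fixture(scope="session")
def scene5():
    """Small non-overlapping scene: 5 crowns in an 800 px raster."""
    return gen_scene(n_crowns=5, size=800, seed=1)


@pytest.fixture(scope="session")
def toy_chips():
    """Trivially separable chips: solid green 'crown' vs earth background."""
    rng = np.random.default_rng(5)
    X, y = [], []
    for i in range(32):
        if i % 2:
            chip = np.stack(
                [rng.normal(0.2, 0.05, (64, 64)),
                 rng.normal(0.8, 0.05, (64, 64)),
                 rng.normal(0.2, 0.05, (64, 64))], axis=-1)
            lab = np.full((64, 64), 255, np.uint8)
        else:
            chip = np.stack(
                [rng.normal(0.5, 0.05, (64, 64)),
                 rng.normal(0.4, 0.05, (64, 64)),
                 rng.normal(0.3, 0.05, (64, 64))], axis=-1)
            lab = np.zeros((64, 64), np.uint8)
        X.append(chip)
        y.append(lab)
    return np.stack(X).astype(np.float32), np.stack(y)
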