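import numpy as np
import pytest

from actinflow import (
    CellMask,
    FlowSpec,
    TextureSpec,
    generate_sequence,
    mask_from_array,
)


@pytest.fixture(scope="session")
def full_mask() -> CellMask:
    """128x128 all-true mask (whole frame is 'cell')."""
    return mask_from_array(np.ones((128, 128), dtype=bool))


@pytest.fixture(scope="session")
def noise_free_texture() -> TextureSpec:
    return TextureSpec(
        photon_noise_scale=0.0, read_noise_std=0.0, bleach_rate_per_frame=0.0
    )


@pytest.fixture(scope="session")
def default_texture() -> TextureSpec:
    return TextureSpec()


def make_uniform_sequence(dx, dy, mask, texture, n_frames=4, seed=3):
    flow = FlowSpec("uniform", {"dx": dx, "dy": dy}, seed=seed)
    return flow, generate_sequence(flow, texture, mask, n_frames)


@pytest.fixture(scope="session")
def speckle_window_bank():
    """Bank of independent random 16x16 speckle windows for correlation tests."""
    rng = np.random.default_rng(42)
    from scipy.ndimage import gaussian_filter

    wins = []
    for _ in range(40):
        img = np.zeros((48, 48))
        n = 30
        ys, xs = rng.integers(0, 48, n), rng.integers(0, 48, n)
        np.add.at(img, (ys, xs), rng.uniform(50, 150, n))
        img = gaussian_filter(img, 1.0, mode="wrap")
        wins.append(img[16:32, 16:32])
    return wins
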