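import numpy as np
import pytest

from spinewave.synthetic import SceneSpec, make_dendrite_image


@pytest.fixture()
def rng():
    # fresh deterministic generator per test: no cross-test order coupling
    return np.random.default_rng(12345)


def strip_image(shape=(64, 64), rows=(30, 37), fg=0.85, bg=0.05, blur=0.7):
    """Horizontal bright strip covering rows[0]:rows[1]; optionally blurred."""
    from scipy.ndimage import gaussian_filter

    img = np.full(shape, bg)
    img[rows[0] : rows[1], :] = fg
    if blur:
        img = gaussian_filter(img, blur)
    return img


def noiseless_dendrite(seed: int, width: float, size: int = 256):
    """Curved noiseless spine-free dendrite with ground truth."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 6)
    rows = 25 + (size - 50) * t
    cols = size / 2 + (size / 3) * np.sin(1.5 * np.pi * t + rng.uniform(0, np.pi))
    spec = SceneSpec(
        height=size,
        width=size,
        control_points=np.column_stack([rows, cols]),
        width_profile=width,
        spines=[],
        gaussian_sigma=0.0,
        poisson_scale=0.0,
        seed=seed,
    )
    return make_dendrite_image(spec)
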