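import numpy as np
import pytest

from mitorhythm import SegmentationParams, SyntheticImageSpec, generate_mito_image


@pytest.fixture(scope="session")
def default_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def noiseless_scene():
    """One noiseless single-cell image with 6 well-separated capsules."""
    spec = SyntheticImageSpec(
        image_size=(160, 160), n_cells=1, mito_per_cell=6, noise_sd=0.0, seed=7, cell_radius_um=5.5
    )
    img, truth = generate_mito_image(spec)
    return spec, img, truth


def make_dumbbell(r: int = 8, gap_bridge: int = 1, shape=(40, 64)) -> np.ndarray:
    """Two discs of radius r joined by a thin bridge: the canonical
    touching-object fixture for the watershed split."""
    mask = np.zeros(shape, bool)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    c1 = (shape[0] // 2, shape[1] // 2 - r - 3)
    c2 = (shape[0] // 2, shape[1] // 2 + r + 3)
    mask |= (yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 <= r**2
    mask |= (yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 <= r**2
    half = (gap_bridge - 1) // 2 + 1
    mask[shape[0] // 2 - half + 1 : shape[0] // 2 + half, c1[1] : c2[1]] = True
    return mask
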