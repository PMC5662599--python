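import numpy as np
import pytest

import fretpolar as fp


@pytest.fixture
def noise_free_params():
    """Polarized cell, no shot or read noise: channel ratio is exact."""
    return fp.SyntheticCellParams(
        n_frames=2, shot_noise=False, read_noise_sd=0.0, rng_seed=0
    )


@pytest.fixture
def noise_free_movie(noise_free_params):
    return fp.generate_polarized_cell_movie(noise_free_params)


@pytest.fixture
def noisy_movie():
    return fp.generate_polarized_cell_movie(
        fp.SyntheticCellParams(n_frames=2, rng_seed=7)
    )


@pytest.fixture
def simple_star():
    params = fp.StarMaskParams(
        body_radius=5.0, arm_lengths=[6.0, 3.0], arm_angles=[0.0, 180.0]
    )
    return fp.generate_star_mask(params)


def true_axis(truth, frame=0):
    return fp.PolarityAxis(
        truth.true_centroid_track[frame], truth.true_front_axis[frame]
    )


@pytest.fixture
def uniform_ratio():
    """A fully defined constant ratio field on a disc mask."""
    H = W = 64
    yy, xx = np.mgrid[0:H, 0:W]
    mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 25 ** 2
    values = np.where(mask, 1.5, np.nan)
    return fp.RatioImage(values=values, defined_mask=mask, normalized=True)
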