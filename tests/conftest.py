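import numpy as np
import pytest

from retinaquant.imaging import RegionOfInterest
from retinaquant.synthetic import SceneConfig


def full_frame_roi(height: int, width: int) -> RegionOfInterest:
    return RegionOfInterest(
        kind="polygon",
        vertices=np.array(
            [
                [-0.5, -0.5],
                [-0.5, width - 0.5],
                [height - 0.5, width - 0.5],
                [height - 0.5, -0.5],
            ]
        ),
        label="full_frame",
    )


def noiseless(**overrides) -> SceneConfig:
    """Scene config with PSF and both noise sources switched off."""
    fields = dict(psf_sigma_um=0.0, shot_noise=False, read_noise_sd=0.0)
    fields.update(overrides)
    return SceneConfig(**fields)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def frame_roi():
    return full_frame_roi
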