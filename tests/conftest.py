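import numpy as np
import pytest

from mpmorph import Micrograph, SceneSpec, ParticleSpec, generate_micrograph


@pytest.fixture()
def flat_micrograph():
    """Uniform mid-gray 8x8 image at 1 um/px."""
    return Micrograph(np.full((8, 8, 3), 0.6), 1.0)


@pytest.fixture()
def two_tone_micrograph():
    """Dark 6x6 square centred on a bright 24x24 background, 1 um/px."""
    img = np.full((24, 24, 3), 0.85)
    img[9:15, 9:15] = 0.3
    return Micrograph(img, 1.0)


@pytest.fixture()
def single_ellipse_scene():
    """One clean 80x40 um ellipse, no background noise, at 1 um/px."""
    spec = SceneSpec(
        shape=(128, 128),
        noise_sigma=0.0,
        gradient_amplitude=0.0,
        particles=(
            ParticleSpec(shape="ellipse", center_um=(64, 64), major_um=80, minor_um=40,
                         orientation_rad=0.4),
        ),
        seed=11,
    )
    return generate_micrograph(spec)
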