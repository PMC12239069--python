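import numpy as np
import pytest

from magcap import CapsuleSpec, ExperimentDesign, FluidMedium, MagnetFieldModel


@pytest.fixture
def field():
    """The reference magnet: 0.27 T surface field, 3 mm decay length."""
    return MagnetFieldModel(surface_field=0.27, decay_length=3e-3)


@pytest.fixture
def fluid():
    return FluidMedium()  # water defaults


@pytest.fixture
def capsule():
    """A 190 um capsule at 500 ppm loading with a mid-range susceptibility."""
    return CapsuleSpec(
        diameter=190e-6,
        np_diameter=10e-9,
        loading_ppm=500.0,
        intrinsic_susceptibility=0.2,
    )


@pytest.fixture
def small_design():
    """A short, cheap acquisition: 4 capsules, 10 s at 24 fps."""
    return ExperimentDesign(
        n_tracks=4,
        frame_rate=24.0,
        duration=10.0,
        start_x_min=1e-3,
        start_x_max=4e-3,
        localization_noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
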