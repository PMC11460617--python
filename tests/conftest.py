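import numpy as np
import pytest

import holopnp as hp


def gaussian_field(size: int = 128, sigma_px: float = 10.0, pitch: float = 1.67,
                   wavelength: float = 627.0) -> hp.ComplexField:
    ax = np.arange(size) - size / 2
    g = np.exp(-np.add.outer(ax**2, ax**2) / (2.0 * sigma_px**2))
    return hp.ComplexField(g.astype(complex), pitch, wavelength)


def hologram_of(phantom: hp.GroundTruthObject, z: float = 1.0,
                wavelength: float = 627.0) -> hp.Hologram:
    cfg = hp.OpticalConfig(wavelength=wavelength, sample_sensor_distance=z,
                           pixel_pitch=phantom.pitch,
                           sensor_shape=phantom.phase.shape)
    return hp.forward_hologram(phantom.to_field(wavelength), cfg)


@pytest.fixture(scope="session")
def cell128():
    """One granular 4-rad cell phantom and its z = 1 mm hologram."""
    ph = hp.make_cell_phantom(128, 1.67, 4.0, seed=1)
    return ph, hologram_of(ph)


@pytest.fixture(scope="session")
def weak_cell64():
    ph = hp.make_cell_phantom(64, 1.67, 2.0, seed=0)
    return ph, hologram_of(ph)
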