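"""Scalar diffraction forward model for lensless inline holography.

Free-space propagation is done with the band-limited angular spectrum
method: the field's spatial spectrum is multiplied by the free-space
transfer function

    K(fx, fy) = exp(i * 2*pi * (z/lambda) * sqrt(1 - (lambda*fx)^2 - (lambda*fy)^2))

with evanescent frequencies (negative square-root argument) zeroed.  The
sign convention is fixed so that propagation over +z followed by -z is the
identity: object-to-sensor propagation uses the positive exponent,
reconstruction (sensor-to-object) the conjugate kernel.

Lengths are handled internally in micrometres; wavelengths cross the API
boundary in nanometres and distances in millimetres, matching how the
acquisition parameters are usually quoted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft as fft

__all__ = [
    "ComplexField",
    "OpticalConfig",
    "Hologram",
    "angular_spectrum_propagate",
    "forward_hologram",
    "normalize_hologram",
    "coherence_limits",
    "field_of_view",
]

NM_PER_UM = 1e3
UM_PER_MM = 1e3


@dataclass
class ComplexField:
    """A sampled 2-D complex wave amplitude.

    Parameters
    ----------
    values : ndarray
        Complex amplitude, dimensionless, shape (rows, cols).
    pitch : float
        Sampling interval in um/pixel.
    wavelength : float
        Vacuum wavelength in nm.
    """

    values: np.ndarray
    pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.iscomplexobj(self.values):
            self.values = self.values.astype(np.complex128)
        if self.values.ndim != 2 or min(self.values.shape) < 8:
            raise ValueError(
                f"field must be 2-D with at least 8 samples per axis, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("field contains non-finite values")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength / NM_PER_UM

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ComplexField":
        return ComplexField(self.values.copy(), self.pitch, self.wavelength)


@dataclass
class OpticalConfig:
    """Acquisition geometry and source parameters of the lensless setup.

    The geometry is the usual inline one: a partially coherent source a few
    centimetres above the sample (z1), the sensor a millimetre or so below
    it (z2), unit magnification, field of view equal to the sensor area.
    """

    wavelength: float = 627.0        # nm
    spectral_width: float = 20.0     # nm, FWHM of the source
    medium_index: float = 1.0
    source_sample_distance: float = 40.0   # z1, mm
    sample_sensor_distance: float = 1.0    # z2, mm
    aperture_diameter: float = 100.0       # D, um (fiber core / pinhole)
    pixel_pitch: float = 1.67              # um
    sensor_shape: tuple[int, int] = (3840, 2784)

    def __post_init__(self) -> None:
        for name in (
            "wavelength",
            "medium_index",
            "source_sample_distance",
            "sample_sensor_distance",
            "aperture_diameter",
            "pixel_pitch",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spectral_width < 0:
            raise ValueError("spectral_width must be non-negative")
        if self.spectral_width >= self.wavelength:
            raise ValueError("spectral_width must be smaller than the wavelength")
        if self.source_sample_distance < 10 * self.sample_sensor_distance:
            warnings.warn(
                "z1 < 10*z2: the plane-wave illumination assumption is questionable",
                stacklevel=2,
            )


@dataclass
class Hologram:
    """A normalized inline hologram: non-negative intensity plus metadata."""

    intensity: np.ndarray
    z2: float          # mm
    wavelength: float  # nm
    pitch: float       # um

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be 2-D")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("hologram intensity contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


def _transfer_function(shape: tuple[int, int], pitch_um: float, wl_um: float,
                       distance_um: float) -> np.ndarray:
    """Angular-spectrum transfer function with hard evanescent cutoff."""
    fy = fft.fftfreq(shape[0], d=pitch_um)[:, None]
    fx = fft.fftfreq(shape[1], d=pitch_um)[None, :]
    arg = 1.0 - (wl_um * fx) ** 2 - (wl_um * fy) ** 2
    prop = arg > 0
    kernel = np.zeros(shape, dtype=np.complex128)
    kernel[prop] = np.exp(
        1j * 2.0 * np.pi * (distance_um / wl_um) * np.sqrt(arg[prop])
    )
    return kernel


def angular_spectrum_propagate(field: ComplexField, distance: float) -> ComplexField:
    """Propagate a field over a signed distance (mm) in free space.

    Positive distances move the field along the optical axis
    (object -> sensor); negative distances apply the conjugate kernel and
    undo a positive propagation exactly on the non-evanescent band.
    """
    if distance == 0.0:
        return field.copy()
    wl_um = field.wavelength_um
    if wl_um / (2.0 * field.pitch) >= 1.0:
        warnings.warn(
            "lambda * Nyquist frequency >= 1: angular spectrum kernel is "
            "aliased at this sampling; proceeding anyway",
            stacklevel=2,
        )
    kernel = _transfer_function(field.shape, field.pitch, wl_um, distance * UM_PER_MM)
    out = fft.ifft2(fft.fft2(field.values) * kernel)
    return ComplexField(out, field.pitch, field.wavelength)


def forward_hologram(object_field: ComplexField, config: OpticalConfig) -> Hologram:
    """Form the normalized inline hologram of an object-plane field.

    The field is the full transmission (unit plane-wave illumination times
    the object), so an empty object is the constant-1 field.  The recorded
    intensity is |propagate(u, z2)|^2, normalized by the no-sample
    reference recording |propagate(1, z2)|^2, which removes the reference
    intensity; the object self-interference remains as part of the
    hologram, as it does on a real sensor.
    """
    z2 = config.sample_sensor_distance
    if z2 <= 0:
        raise ValueError("sample_sensor_distance must be positive")
    sensor = angular_spectrum_propagate(object_field, z2)
    raw = np.abs(sensor.values) ** 2
    ref_field = ComplexField(
        np.ones(object_field.shape, dtype=np.complex128),
        object_field.pitch,
        object_field.wavelength,
    )
    reference = np.abs(angular_spectrum_propagate(ref_field, z2).values) ** 2
    return normalize_hologram(
        raw, reference, z2=z2, wavelength=object_field.wavelength,
        pitch=object_field.pitch,
    )


def normalize_hologram(raw: np.ndarray, reference: np.ndarray, *, z2: float,
                       wavelength: float, pitch: float) -> Hologram:
    """Divide a raw recording by the no-sample reference recording.

    Reference pixels below 1e-6 of the reference maximum are floored to
    that level; the number of floored pixels is reported via a warning.
    """
    raw = np.asarray(raw, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if raw.shape != reference.shape:
        raise ValueError(f"shape mismatch: raw {raw.shape} vs reference {reference.shape}")
    floor = 1e-6 * reference.max()
    if floor <= 0:
        raise ValueError("reference image is not strictly positive anywhere")
    n_floored = int(np.count_nonzero(reference < floor))
    if n_floored:
        warnings.warn(
            f"{n_floored} reference pixels below floor {floor:.3g}; floored",
            stacklevel=2,
        )
    return Hologram(raw / np.maximum(reference, floor), z2=z2,
                    wavelength=wavelength, pitch=pitch)


def coherence_limits(config: OpticalConfig) -> dict[str, float]:
    """Coherence-limited resolution figures of the partially coherent source.

    Returns temporal coherence length ``delta_Lc`` (um), spatial coherence
    diameter ``D_coh`` (um) at the sample plane, the two maximum accepted
    hologram cone angles (rad), and a conservative resolution estimate
    ``delta_x`` (um) from the smaller of the two angles.
    """
    wl_um = config.wavelength / NM_PER_UM
    dl_um = config.spectral_width / NM_PER_UM
    z1_um = config.source_sample_distance * UM_PER_MM
    z2_um = config.sample_sensor_distance * UM_PER_MM
    if dl_um == 0.0:
        delta_lc = np.inf
    else:
        delta_lc = (2.0 * np.log(2.0) / np.pi) * wl_um**2 / (config.medium_index * dl_um)
    d_coh = wl_um * z1_um / config.aperture_diameter
    theta_temporal = (
        np.pi / 2.0 if np.isinf(delta_lc) else float(np.arccos(z2_um / (z2_um + delta_lc)))
    )
    theta_spatial = float(
        np.arctan(0.61 * wl_um * z1_um / (config.aperture_diameter * z2_um))
    )
    theta = min(theta_temporal, theta_spatial)
    delta_x = np.inf if theta == 0.0 else wl_um / (2.0 * np.sin(theta))
    return {
        "delta_Lc": float(delta_lc),
        "D_coh": float(d_coh),
        "theta_max_temporal": theta_temporal,
        "theta_max_spatial": theta_spatial,
        "delta_x": float(delta_x),
    }


def field_of_view(config: OpticalConfig) -> float:
    """Sensor-limited field of view in mm^2 (unit-magnification geometry)."""
    rows, cols = config.sensor_shape
    return rows * config.pixel_pitch * cols * config.pixel_pitch / UM_PER_MM**2
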