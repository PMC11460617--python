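"""Reading and writing holograms, phase maps, and complex fields.

Holograms travel as 16-bit grayscale TIFF/PNG with a YAML sidecar carrying
the acquisition parameters (z2 in mm, wavelength in nm, pixel pitch in um).
Phase maps are 32-bit float TIFF in radians.  Complex fields are stored in
an HDF5 container with datasets ``real``/``imag`` and attributes
``pitch_um``/``wavelength_nm``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .wave_optics import ComplexField, Hologram

__all__ = [
    "write_hologram",
    "read_hologram",
    "write_phase",
    "read_phase",
    "write_field",
    "read_field",
]

_U16_MAX = 65535


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_hologram(path: str | Path, holo: Hologram) -> None:
    """Write a hologram as 16-bit TIFF plus a YAML metadata sidecar.

    Intensity is scaled by its maximum into the uint16 range; the scale is
    recorded in the sidecar so reading is lossless up to quantization.
    """
    path = Path(path)
    scale = float(holo.intensity.max())
    if scale == 0.0:
        scale = 1.0
    raw = np.round(holo.intensity / scale * _U16_MAX).astype(np.uint16)
    tifffile.imwrite(path, raw)
    meta = {
        "z2_mm": float(holo.z2),
        "wavelength_nm": float(holo.wavelength),
        "pitch_um": float(holo.pitch),
        "intensity_scale": scale,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def read_hologram(path: str | Path) -> Hologram:
    path = Path(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    raw = tifffile.imread(path).astype(np.float64)
    intensity = raw / _U16_MAX * meta["intensity_scale"]
    return Hologram(intensity, z2=meta["z2_mm"], wavelength=meta["wavelength_nm"],
                    pitch=meta["pitch_um"])


def write_phase(path: str | Path, phase: np.ndarray) -> None:
    """Write a phase map (radians) as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(phase, dtype=np.float32))


def read_phase(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def write_field(path: str | Path, field: ComplexField) -> None:
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("real", data=field.values.real.astype(np.float32))
        f.create_dataset("imag", data=field.values.imag.astype(np.float32))
        f.attrs["pitch_um"] = field.pitch
        f.attrs["wavelength_nm"] = field.wavelength


def read_field(path: str | Path) -> ComplexField:
    with h5py.File(Path(path), "r") as f:
        values = f["real"][()].astype(np.float64) + 1j * f["imag"][()].astype(np.float64)
        return ComplexField(values, float(f.attrs["pitch_um"]),
                            float(f.attrs["wavelength_nm"]))
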