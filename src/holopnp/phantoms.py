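"""Seeded synthetic ground-truth objects and hologram datasets.

Two phantom families cover the scenarios the downstream reconstruction is
scored on:

* polystyrene-like microbeads — pure-phase spherical caps with a known
  peak phase 2*pi*h*(n1-n2)/lambda, used for thickness characterization;
* cell-like blobs — a granular cytoplasm with denser nuclei,
  rescaled to a prescribed peak phase, emulating the simulation protocol
  used for training-set generation (diffraction patterns at z drawn from
  {0.8 ... 1.3} mm, lambda = 627 nm, peak phase 4 rad).

Everything is a pure function of its arguments and a seed.

A note on bead edges: the thickness of a sphere has an infinite radial
derivative at its rim, so a literally sampled 14-rad bead can never be
2-D phase unwrapped (neighbouring samples would always differ by more
than pi somewhere on the rim).  Beads are therefore rendered with a
resolution-matched Gaussian-soft edge, and the profile is rescaled so the
center thickness — the quantity the thickness formula reads out — is
exact to machine precision.  This mirrors what any finite-resolution
instrument does to a bead edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from . import io as hio
from .wave_optics import ComplexField, Hologram, OpticalConfig, forward_hologram

__all__ = [
    "GroundTruthObject",
    "DatasetSpec",
    "bead_peak_phase",
    "make_bead_phantom",
    "make_cell_phantom",
    "build_dataset",
    "split_sizes",
    "downsample_sensor",
    "add_noise",
    "degrade_phase_prior",
]


@dataclass
class GroundTruthObject:
    """Phantom amplitude/phase maps plus the physical parameters behind them."""

    phase: np.ndarray          # radians
    amplitude: np.ndarray      # in [0, 1]
    pitch: float               # um
    physical_params: dict | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase contains non-finite values")
        if np.any(self.amplitude < 0) or np.any(self.amplitude > 1):
            raise ValueError("amplitude must lie in [0, 1]")

    def to_field(self, wavelength: float) -> ComplexField:
        """Object transmission under unit plane-wave illumination."""
        return ComplexField(self.amplitude * np.exp(1j * self.phase),
                            self.pitch, wavelength)


@dataclass
class DatasetSpec:
    """Recipe for a seeded synthetic hologram dataset."""

    n_total: int = 2048
    split_fractions: tuple[float, float, float] = (1800 / 2048, 148 / 2048, 100 / 2048)
    z_choices: tuple[float, ...] = (0.8, 0.9, 1.0, 1.1, 1.2, 1.3)  # mm
    wavelength: float = 627.0   # nm
    peak_phase: float = 4.0     # rad
    pitch: float = 1.67         # um
    image_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not self.z_choices:
            raise ValueError("z_choices must be non-empty")


def bead_peak_phase(diameter: float, n1: float, n2: float, wavelength: float) -> float:
    """Peak phase delay of a sphere: 2*pi*diameter*(n1 - n2)/lambda (lambda in nm)."""
    return 2.0 * np.pi * diameter * (n1 - n2) / (wavelength / 1e3)


def _auto_edge_sigma(peak_phase: float, pitch: float) -> float:
    # Keep the steepest per-pixel phase increment of the rendered profile
    # below ~0.65*pi: the local spatial frequency then stays well inside
    # the sensor band, so the object is resolvable at this pitch, its
    # resolution-limited apex loss is small, and 2-D unwrapping is well
    # posed.  For a Gaussian-shaped bump of height P and width s,
    # max |dphi/dr| = P/(s*sqrt(e)).
    s = abs(peak_phase) * pitch / (0.65 * np.pi * np.sqrt(np.e))
    return max(pitch, s)


def make_bead_phantom(n_beads: int, bead_diameter: float, n1: float, n2: float,
                      wavelength: float, pitch: float, size: int, seed: int,
                      edge_sigma: float | None = None) -> GroundTruthObject:
    """Pure-phase phantom of non-overlapping spherical beads.

    Parameters are physical: ``bead_diameter`` and ``pitch`` in um,
    ``wavelength`` in nm.  Bead centers land on pixel centers; the phase at
    each center equals the closed form exactly after edge softening.
    """
    if bead_diameter < 2 * pitch:
        raise ValueError("bead_diameter must be at least 2 pixels across")
    rng = np.random.default_rng(seed)
    radius_um = bead_diameter / 2.0
    peak = bead_peak_phase(bead_diameter, n1, n2, wavelength)
    if edge_sigma is None:
        edge_sigma = _auto_edge_sigma(peak, pitch)
    # exclusion zone: bead plus the softened skirt
    margin_px = int(np.ceil((radius_um + 4.0 * edge_sigma) / pitch))
    if 2 * margin_px >= size:
        raise ValueError(
            f"grid of {size} px cannot hold a bead with margin {margin_px} px"
        )
    min_sep_px = 2 * margin_px
    centers: list[tuple[int, int]] = []
    for _ in range(10000):
        if len(centers) == n_beads:
            break
        c = tuple(rng.integers(margin_px, size - margin_px, 2))
        if all((c[0] - a) ** 2 + (c[1] - b) ** 2 >= min_sep_px**2 for a, b in centers):
            centers.append(c)
    else:
        raise RuntimeError(
            f"could not place {n_beads} non-overlapping beads of diameter "
            f"{bead_diameter} um on a {size}x{size} grid at pitch {pitch} um"
        )

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    thickness = np.zeros((size, size))
    for cy, cx in centers:
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) * pitch**2
        inside = r2 < radius_um**2
        cap = np.zeros_like(thickness)
        cap[inside] = bead_diameter * np.sqrt(1.0 - r2[inside] / radius_um**2)
        thickness += cap
    if edge_sigma > 0:
        thickness = gaussian_filter(thickness, sigma=edge_sigma / pitch, mode="constant")
    # renormalize so bead centers carry the exact closed-form thickness
    top = thickness[centers[0][0], centers[0][1]]
    if top > 0:
        thickness *= bead_diameter / top
    phase = 2.0 * np.pi * thickness * (n1 - n2) / (wavelength / 1e3)
    return GroundTruthObject(
        phase=phase,
        amplitude=np.ones_like(phase),
        pitch=pitch,
        physical_params={
            "h": bead_diameter, "n1": n1, "n2": n2,
            "wavelength_nm": wavelength, "bead_diameter_um": bead_diameter,
            "centers_px": [list(map(int, c)) for c in centers],
            "edge_sigma_um": float(edge_sigma),
        },
    )


def make_cell_phantom(size: int, pitch: float, peak_phase: float,
                      seed: int, granularity: float = 0.12,
                      absorption: float = 0.0) -> GroundTruthObject:
    """Cell-like phase blob: cytoplasm, nuclei, and fine granules.

    The phase map is band-limited by Gaussian smoothing and rescaled so its
    maximum equals ``peak_phase`` exactly (blank if ``peak_phase`` is 0).
    ``granularity`` sets the relative strength of few-pixel-scale organelle
    texture inside the cytoplasm; a feature of size a defocuses over
    z ~ a^2/lambda, so this fine texture is what gives holograms of smooth
    cells a usable autofocus signature at millimetre distances.

    ``absorption`` adds a weakly absorbing amplitude component (smooth dip
    plus sharp granular absorption inside the cell, amplitude clipped to
    [0, 1]); the default is a pure-phase object.
    """
    if peak_phase < 0:
        raise ValueError("peak_phase must be non-negative")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy, cx = rng.uniform(0.35 * size, 0.65 * size, 2)
    ry, rx = rng.uniform(0.13 * size, 0.28 * size, 2)
    angle = rng.uniform(0.0, np.pi)
    ca, sa = np.cos(angle), np.sin(angle)
    u = (yy - cy) * ca + (xx - cx) * sa
    v = -(yy - cy) * sa + (xx - cx) * ca
    theta = np.arctan2(v, u)
    # low-order boundary perturbation so no two seeds give the same outline
    wobble = np.ones_like(theta)
    for m in range(2, 7):
        wobble += rng.uniform(-0.12, 0.12) * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
    rho = np.sqrt((u / ry) ** 2 + (v / rx) ** 2) / wobble
    phase = np.clip(1.0 - rho, 0.0, None) ** 0.7

    n_nuclei = rng.integers(1, 4)
    for _ in range(n_nuclei):
        off = rng.uniform(-0.3, 0.3, 2)
        ncy, ncx = cy + off[0] * ry, cx + off[1] * rx
        nr = rng.uniform(0.2, 0.35) * min(ry, rx)
        r2 = (yy - ncy) ** 2 + (xx - ncx) ** 2
        phase += 1.6 * np.exp(-r2 / (2.0 * nr**2))

    phase = gaussian_filter(phase, sigma=max(2.0, size / 85.0))

    if granularity > 0:
        mask = np.clip(1.0 - rho, 0.0, None)
        mask = mask / mask.max() if mask.max() > 0 else mask
        texture = gaussian_filter(rng.standard_normal((size, size)), sigma=1.3)
        texture /= max(np.abs(texture).max(), 1e-12)
        phase = phase * (1.0 + granularity * texture * mask)
        phase = np.clip(phase, 0.0, None)

    top = phase.max()
    phase = phase * (peak_phase / top) if top > 0 and peak_phase > 0 else np.zeros_like(phase)

    amplitude = np.ones_like(phase)
    if absorption > 0:
        mask = np.clip(1.0 - rho, 0.0, None)
        if mask.max() > 0:
            mask = mask / mask.max()
        sharp = gaussian_filter(rng.standard_normal((size, size)), sigma=1.2)
        sharp /= max(np.abs(sharp).max(), 1e-12)
        amplitude = np.clip(
            1.0 - absorption * (0.7 * mask + np.clip(sharp, 0.0, None) * (mask > 0.1)),
            0.0, 1.0)
    return GroundTruthObject(phase=phase, amplitude=amplitude, pitch=pitch)


def degrade_phase_prior(phase: np.ndarray, upsample_factor: int = 2,
                        blur_sigma: float = 1.5) -> np.ndarray:
    """Synthetic stand-in for the output of an externally trained
    high-resolution phase estimator.

    A trained generator produces a phase map that is approximately right
    but band-limited and slightly smoothed relative to the truth.  This
    helper emulates that: the ground-truth phase is resampled to the
    upsampled reconstruction grid and Gaussian-blurred, so downstream code
    receives a plausible — not perfect — learned prior.
    """
    from skimage.transform import resize

    out = np.asarray(phase, dtype=np.float64)
    if upsample_factor != 1:
        shape = tuple(s * upsample_factor for s in out.shape)
        out = resize(out, shape, order=3, mode="edge", preserve_range=True)
    if blur_sigma > 0:
        out = gaussian_filter(out, sigma=blur_sigma)
    return out


def split_sizes(n_total: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Train/val sizes floor, remainder to test."""
    n_train = int(np.floor(fractions[0] * n_total))
    n_val = int(np.floor(fractions[1] * n_total))
    return n_train, n_val, n_total - n_train - n_val


def build_dataset(spec: DatasetSpec, out_dir: str | Path) -> dict:
    """Write paired hologram/phase images plus a YAML manifest.

    Layout: ``holograms/<split>/NNNN.tiff`` and ``phases/<split>/NNNN.tiff``
    carry the same record name; the manifest echoes the spec and records
    the per-record z, seed and relative paths.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    record_seeds = rng.integers(0, 2**31 - 1, spec.n_total)
    zs = rng.choice(spec.z_choices, size=spec.n_total)
    n_train, n_val, n_test = split_sizes(spec.n_total, tuple(spec.split_fractions))
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test

    records = []
    manifest = {
        "spec": {
            "n_total": spec.n_total,
            "split_fractions": list(spec.split_fractions),
            "z_choices": list(spec.z_choices),
            "wavelength_nm": spec.wavelength,
            "peak_phase_rad": spec.peak_phase,
            "pitch_um": spec.pitch,
            "image_size": spec.image_size,
            "seed": spec.seed,
        },
        "records": records,
    }
    try:
        for i in range(spec.n_total):
            name = f"{i:04d}.tiff"
            split = splits[i]
            phantom = make_cell_phantom(spec.image_size, spec.pitch,
                                        spec.peak_phase, int(record_seeds[i]))
            config = OpticalConfig(wavelength=spec.wavelength,
                                   sample_sensor_distance=float(zs[i]),
                                   pixel_pitch=spec.pitch,
                                   sensor_shape=(spec.image_size, spec.image_size))
            holo = forward_hologram(phantom.to_field(spec.wavelength), config)
            holo_path = out_dir / "holograms" / split / name
            phase_path = out_dir / "phases" / split / name
            holo_path.parent.mkdir(parents=True, exist_ok=True)
            phase_path.parent.mkdir(parents=True, exist_ok=True)
            hio.write_hologram(holo_path, holo)
            hio.write_phase(phase_path, phantom.phase)
            records.append({
                "name": name, "split": split, "z_mm": float(zs[i]),
                "seed": int(record_seeds[i]),
                "hologram": str(holo_path.relative_to(out_dir)),
                "phase": str(phase_path.relative_to(out_dir)),
                "complete": True,
            })
    finally:
        (out_dir / "manifest.yaml").parent.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest


def downsample_sensor(holo: Hologram, factor: int) -> Hologram:
    """Emulate a coarser sensor by factor x factor pixel-mean binning."""
    if factor == 1:
        return Hologram(holo.intensity.copy(), holo.z2, holo.wavelength, holo.pitch)
    rows, cols = holo.shape
    if rows % factor or cols % factor:
        raise ValueError(f"factor {factor} does not divide shape {holo.shape}")
    binned = holo.intensity.reshape(rows // factor, factor,
                                    cols // factor, factor).mean(axis=(1, 3))
    return Hologram(binned, holo.z2, holo.wavelength, holo.pitch * factor)


def add_noise(holo: Hologram, shot_scale: float, read_sigma: float,
              seed: int) -> Hologram:
    """Poisson shot noise at ``shot_scale`` photons per unit intensity plus
    additive Gaussian read noise, clipped at zero."""
    if shot_scale < 0 or read_sigma < 0:
        raise ValueError("noise parameters must be non-negative")
    rng = np.random.default_rng(seed)
    out = holo.intensity.copy()
    if shot_scale > 0:
        out = rng.poisson(out * shot_scale).astype(np.float64) / shot_scale
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, out.shape)
    return Hologram(np.clip(out, 0.0, None), holo.z2, holo.wavelength, holo.pitch)
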