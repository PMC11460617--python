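"""Quantitative evaluation of reconstructed phase images.

Metrics: structural similarity (SSIM, Gaussian-weighted 11-pixel window),
mean squared error, and the phase signal-to-noise ratio

    p-SNR = 10 * log10[(max(P) - mu) / sigma]   (dB)

with mu the mean and sigma the standard deviation of the phase image P.
(sigma is the standard deviation rather than the variance so the log
argument is a dimensionless amplitude ratio.)  Phase converts to physical
thickness through h = p * lambda / (2*pi*(n1 - n2)).

`sweep` runs a battery of phantoms through one or more reconstruction
methods while varying the propagation distance (or wavelength) and
reports per-cell metrics plus the width of each method's peak-performance
interval, defined as the axis range where mean SSIM stays within 95% of
its maximum.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity

from .classic import backpropagate, extract_amp_phase
from .generator import GeneratorSpec
from .phantoms import GroundTruthObject
from .pnp import ADMMConfig, reconstruct
from .wave_optics import OpticalConfig, forward_hologram

__all__ = ["EvalReport", "psnr_phase", "ssim", "mse", "thickness_map", "sweep"]


def psnr_phase(P: np.ndarray, roi: tuple[slice, slice] | None = None) -> float:
    """Phase SNR in dB; +inf for a constant image (sigma = 0)."""
    P = np.asarray(P, dtype=np.float64)
    if roi is not None:
        P = P[roi]
    if not np.all(np.isfinite(P)):
        raise ValueError("phase image contains non-finite values")
    sigma = P.std()
    if sigma == 0.0:
        return float("inf")
    return float(10.0 * np.log10((P.max() - P.mean()) / sigma))


def ssim(phase: np.ndarray, reference: np.ndarray) -> float:
    """Gaussian-windowed SSIM with data range taken from the reference."""
    phase = np.asarray(phase, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if phase.shape != reference.shape:
        raise ValueError(f"shape mismatch {phase.shape} vs {reference.shape}")
    rng = float(reference.max() - reference.min())
    if rng == 0.0:
        rng = 1.0
    return float(structural_similarity(reference, phase, data_range=rng,
                                       gaussian_weights=True, win_size=11,
                                       sigma=1.5, K1=0.01, K2=0.03))


def mse(phase: np.ndarray, reference: np.ndarray) -> float:
    phase = np.asarray(phase, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if phase.shape != reference.shape:
        raise ValueError(f"shape mismatch {phase.shape} vs {reference.shape}")
    return float(np.mean((phase - reference) ** 2))


def thickness_map(phase: np.ndarray, wavelength: float, n1: float,
                  n2: float) -> np.ndarray:
    """Convert unwrapped phase (rad) to thickness (um); wavelength in nm."""
    if n1 == n2:
        raise ValueError("n1 must differ from n2")
    return np.asarray(phase, dtype=np.float64) * (wavelength / 1e3) / (
        2.0 * np.pi * (n1 - n2))


@dataclass
class EvalReport:
    axis: str
    values: list[float]
    methods: list[str]
    rows: list[dict] = dc_field(default_factory=list)

    def aggregate(self) -> dict[tuple[str, float], dict[str, float]]:
        """Mean/std of each metric per (method, axis value)."""
        out: dict[tuple[str, float], dict[str, float]] = {}
        for m in self.methods:
            for v in self.values:
                sel = [r for r in self.rows
                       if r["method"] == m and r["value"] == v]
                if not sel:
                    continue
                cell = {}
                for key in ("ssim", "mse", "psnr_phase"):
                    arr = np.array([r[key] for r in sel])
                    cell[f"{key}_mean"] = float(arr.mean())
                    cell[f"{key}_std"] = float(arr.std())
                    cell["n"] = len(sel)
                out[(m, v)] = cell
        return out

    def peak_interval(self, method: str, frac: float = 0.95) -> tuple[float, float]:
        """Axis interval where mean SSIM stays within ``frac`` of its peak."""
        agg = self.aggregate()
        vals = sorted(v for (m, v) in agg if m == method)
        curve = np.array([agg[(method, v)]["ssim_mean"] for v in vals])
        keep = curve >= frac * curve.max()
        kept = [v for v, k in zip(vals, keep) if k]
        return (min(kept), max(kept))

    def to_csv(self, path: str | Path) -> None:
        if not self.rows:
            raise ValueError("empty report")
        keys = list(self.rows[0])
        with open(path, "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=keys)
            w.writeheader()
            w.writerows(self.rows)

    def to_json(self, path: str | Path) -> None:
        agg = {f"{m}@{v}": cell for (m, v), cell in self.aggregate().items()}
        Path(path).write_text(json.dumps(
            {"axis": self.axis, "values": self.values, "methods": self.methods,
             "aggregate": agg}, indent=2))


def _reconstruct_one(holo, method: str, z: float, config: ADMMConfig,
                     gen_spec: GeneratorSpec, prior_phase=None) -> np.ndarray:
    if method == "asm":
        return extract_amp_phase(backpropagate(holo, z), unwrap=True)["phase"]
    return reconstruct(holo, method, config=config, gen_spec=gen_spec,
                       prior_phase=prior_phase, z=z)["phase"]


def sweep(phantoms: list[GroundTruthObject], methods: list[str], axis: str,
          values: list[float], *, wavelength: float = 627.0,
          z2: float = 1.0, config: ADMMConfig | None = None,
          configs: dict[str, ADMMConfig] | None = None,
          gen_spec: GeneratorSpec | None = None,
          prior_phases: list[np.ndarray] | None = None) -> EvalReport:
    """Robustness sweep over propagation distance or wavelength.

    For each axis value a fresh noiseless hologram of every phantom is
    formed and reconstructed by every method at the true distance; SSIM
    and MSE are scored against the ground-truth phase.  ``configs`` may
    override the shared ``config`` per method (the sensible weights differ
    between a prior-free and a prior-driven run).
    """
    if axis not in ("z", "lambda"):
        raise ValueError("axis must be 'z' or 'lambda'")
    config = config or ADMMConfig()
    configs = configs or {}
    gen_spec = gen_spec or GeneratorSpec(seed=config.seed)
    report = EvalReport(axis=axis, values=list(values), methods=list(methods))
    for v in values:
        z = v if axis == "z" else z2
        wl = wavelength if axis == "z" else v
        for i, phantom in enumerate(phantoms):
            cfg = OpticalConfig(wavelength=wl, sample_sensor_distance=z,
                                pixel_pitch=phantom.pitch,
                                sensor_shape=phantom.phase.shape)
            holo = forward_hologram(phantom.to_field(wl), cfg)
            gt = phantom.phase
            for method in methods:
                pp = prior_phases[i] if (prior_phases is not None
                                         and method == "hybrid") else None
                phase = _reconstruct_one(holo, method, z,
                                         configs.get(method, config), gen_spec,
                                         prior_phase=pp)
                report.rows.append({
                    "method": method, "axis": axis, "value": float(v),
                    "phantom": i, "ssim": ssim(phase, gt),
                    "mse": mse(phase, gt), "psnr_phase": psnr_phase(phase),
                })
    return report
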