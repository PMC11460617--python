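"""Independent reference implementations used only as test oracles.

These deliberately avoid the production code paths: propagation is done
by direct spatial-domain quadrature of the Rayleigh-Sommerfeld integral
(an O(N^4) sum realized as an explicit linear convolution), and the ADMM
updates are re-derived as scalar recursions.
"""

from __future__ import annotations

import numpy as np
import scipy.signal


def rayleigh_sommerfeld_propagate(u: np.ndarray, pitch_um: float,
                                  wavelength_um: float, z_um: float) -> np.ndarray:
    """Direct quadrature of the first Rayleigh-Sommerfeld diffraction
    integral: convolution with h = (z/(i*lambda)) (1 + i/(k*rho))
    exp(i*k*rho)/rho^2 sampled on the displacement grid."""
    n = u.shape[0]
    k = 2.0 * np.pi / wavelength_um
    ax = np.arange(-(n - 1), n) * pitch_um
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    rho = np.sqrt(X**2 + Y**2 + z_um**2)
    h = z_um / (1j * wavelength_um) * np.exp(1j * k * rho) / rho**2 * (
        1.0 + 1j / (k * rho))
    return scipy.signal.convolve2d(u, h * pitch_um**2, mode="same",
                                   boundary="fill")


def scalar_object_updates(uo0: complex, u_tau: complex, R: complex, t0: complex,
                          alpha: float, beta: float, c: float,
                          n_steps: int) -> list[complex]:
    """Hand-iterated explicit object update with R, t frozen."""
    uo = uo0
    out = []
    for _ in range(n_steps):
        uo = uo - c * (alpha * (uo - u_tau) + beta * (uo - R - t0))
        out.append(uo)
    return out


def scalar_multiplier_updates(t0: complex, uo: complex, R: complex,
                              gamma: float, n_steps: int,
                              sign: str = "residual") -> list[complex]:
    """Hand-iterated multiplier update with uo, R frozen."""
    t = t0
    out = []
    for _ in range(n_steps):
        if sign == "residual":
            t = t - gamma * (uo - R)
        else:
            t = t - gamma * (uo + R)
        out.append(t)
    return out
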