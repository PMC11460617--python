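"""Plug-and-play ADMM phase retrieval with an untrained generator.

The reconstruction minimizes, over the complex object estimate ``uo`` and
the generator parameters ``theta``,

    L(theta, uo, t) = 1/2 ||H(R_theta(uo)) - I_tau||^2
                    + alpha/2 * Re<uo, uo - u_tau>
                    + beta/2  * ||uo - R_theta(uo) - t||^2

where H is the hologram forward model at the focused distance, ``I_tau``
the (optionally upsampled) measured hologram, ``u_tau`` a complex object
built from an externally supplied or surrogate high-resolution phase
prior, and ``t`` the ADMM multiplier field.  One outer epoch performs the
sequential updates

    theta  <- gradient steps on the fidelity + proximity terms,
    uo     <- uo - c*[alpha*(uo - u_tau) + beta*(uo - R_theta(uo) - t)],
    t      <- t - gamma*(uo - R_theta(uo)),

and stops when the per-pixel change of all three sub-objectives falls
below tol/3, or at the epoch cap.

Numerical choices that matter (see docs/methods.md for the full account):

* The object step uses c = 1/(alpha + beta) by default, which makes the
  explicit step the exact minimizer of the quadratic object sub-problem.
  An under-relaxed object step combined with a full multiplier step is
  unstable: the multiplier integrates the splitting residual faster than
  the object can discharge it.
* The multiplier step is damped (gamma < 1) because the theta
  sub-problem is solved inexactly (a single Adam step per epoch).
* A single-shot intensity constrains only the sensor-plane modulus, so
  the data term alone admits a manifold of perfect-fit solutions; the
  prior term (constant-amplitude u_tau) supplies the object-domain
  constraint that selects a physically meaningful one.
* The returned object is the average of the iterates over the last
  ``avg_tail`` epochs: the inexact sub-steps leave a small limit cycle,
  and iterate averaging removes it.
* When a prior phase is available, the output phase is unwrapped against
  it as a reference surface (phi_tau + wrapped difference), which keeps
  the winding count of strong-phase objects out of the fragile 2-D
  unwrapping path.

The multiplier update is the constraint-residual form: the proximity term
penalizes ``uo - R(uo) - t``, so only a difference residual vanishes at
the splitting fixed point.  A ``multiplier_sign="sum"`` switch implements
the sum form ``t - (uo + R(uo))`` for comparison.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.fft as fft
from skimage.restoration import denoise_tv_chambolle
from skimage.transform import resize

from . import generator as gen
from .autodiff import Adam, Tensor, square_sum
from .classic import autofocus, backpropagate, border_mode, extract_amp_phase
from .generator import GeneratorSpec
from .wave_optics import ComplexField, Hologram, UM_PER_MM
from .wave_optics import _transfer_function

__all__ = ["PriorBundle", "ADMMConfig", "ADMMState", "make_prior", "initialize",
           "loss", "hologram_fidelity", "update_theta", "update_object",
           "update_multiplier", "check_convergence", "reconstruct"]

MODES = ("dip", "dip-red", "hybrid")


@dataclass
class PriorBundle:
    """High-resolution prior: phase, hologram, and the complex object built
    from them; ``mode`` records where the phase came from."""

    phi_tau: np.ndarray       # radians, upsampled grid
    I_tau: np.ndarray         # upsampled hologram intensity
    u_tau: np.ndarray         # complex, constant amplitude * exp(i*phi_tau)
    mode: str                 # file | tv | bicubic | none
    upsample_factor: int
    pitch: float              # um, upsampled grid
    wavelength: float         # nm
    z: float                  # mm, focused distance
    alpha_disabled: bool = False


@dataclass
class ADMMConfig:
    """Weights, step sizes and stopping rule of the ADMM loop.

    ``tol`` follows the stopping rule (max sub-objective drift <= tol/3).
    The default c equals 1/(alpha + beta), the exact solve of the object
    sub-problem; the remaining defaults were fixed once by a coarse grid
    search on a single noiseless validation phantom.
    """

    alpha: float = 0.4          # prior weight
    beta: float = 0.6           # proximity weight
    c: float = 1.0              # object step; 1/(alpha+beta) = exact solve
    theta_lr: float = 5e-4      # Adam learning rate for the generator
    tol: float = 1e-3
    max_epochs: int = 700
    inner_theta_steps: int = 1
    seed: int = 0
    multiplier_sign: str = "residual"   # "residual" | "sum"
    multiplier_step: float = 0.3        # damping gamma of the t update
    tv_weight: float = 0.05
    avg_tail: int = 50                  # iterate-averaging window

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.c <= 0 or self.tol <= 0:
            raise ValueError("c and tol must be positive")
        if not 0 < self.multiplier_step <= 1:
            raise ValueError("multiplier_step must be in (0, 1]")
        if self.multiplier_sign not in ("residual", "sum"):
            raise ValueError("multiplier_sign must be 'residual' or 'sum'")


@dataclass
class ADMMState:
    uo: np.ndarray                     # complex object estimate
    t: np.ndarray                      # complex multiplier field
    params: dict[str, Tensor]          # generator parameters theta
    gen_spec: GeneratorSpec
    kernel: np.ndarray                 # forward transfer function at +z
    k: int = 0
    R: np.ndarray | None = None        # cached R_theta(uo^k)
    lr_halvings: int = 0
    residuals: list[tuple[float, float, float]] = dc_field(default_factory=list)
    loss_history: list[dict[str, float]] = dc_field(default_factory=list)
    sub_objectives: list[tuple[float, float, float]] = dc_field(default_factory=list)
    flags: list[str] = dc_field(default_factory=list)


# ---------------------------------------------------------------------------

def _to_2ch(u: np.ndarray) -> np.ndarray:
    return np.stack([u.real, u.imag]).astype(np.float32)


def _to_complex(x2: np.ndarray) -> np.ndarray:
    return x2[0].astype(np.float64) + 1j * x2[1].astype(np.float64)


def make_prior(hologram: Hologram, mode: str, upsample_factor: int, z: float,
               prior_phase: np.ndarray | None = None,
               tv_weight: float = 0.05) -> PriorBundle:
    """Assemble the prior bundle for one reconstruction.

    ``I_tau`` is always the bicubically upsampled measured hologram.  The
    prior phase depends on ``mode``: an externally produced file
    (radians, upsampled shape), a total-variation denoised back-propagation,
    a bicubically upsampled back-propagated phase, or all-zero (``none``,
    which disables the prior term).
    """
    if upsample_factor not in (1, 2, 4):
        raise ValueError("upsample_factor must be 1, 2 or 4")
    up_shape = tuple(s * upsample_factor for s in hologram.shape)
    if upsample_factor == 1:
        I_tau = hologram.intensity.copy()
    else:
        I_tau = resize(hologram.intensity, up_shape, order=3, mode="edge",
                       anti_aliasing=False, preserve_range=True)
        I_tau = np.clip(I_tau, 0.0, None)
    pitch_tau = hologram.pitch / upsample_factor
    holo_tau = Hologram(I_tau, hologram.z2, hologram.wavelength, pitch_tau)
    uo0 = backpropagate(holo_tau, z)
    alpha_disabled = False

    if mode == "none":
        phi_tau = np.zeros(up_shape)
        alpha_disabled = True
    elif mode == "file":
        if prior_phase is None:
            raise ValueError("mode='file' requires prior_phase")
        prior_phase = np.asarray(prior_phase, dtype=np.float64)
        if prior_phase.shape != up_shape:
            raise ValueError(
                f"prior_phase shape {prior_phase.shape} does not match the "
                f"upsampled grid {up_shape}")
        phi_tau = prior_phase
    elif mode == "tv":
        phi0 = extract_amp_phase(uo0, unwrap=True)["phase"]
        phi_tau = denoise_tv_chambolle(phi0, weight=tv_weight)
    elif mode == "bicubic":
        base = backpropagate(hologram, z)
        phi0 = extract_amp_phase(base, unwrap=True)["phase"]
        phi_tau = phi0 if upsample_factor == 1 else resize(
            phi0, up_shape, order=3, mode="edge", preserve_range=True)
    else:
        raise ValueError(f"unknown prior mode {mode!r}")

    amp0 = float(np.mean(np.abs(uo0.values)))
    u_tau = amp0 * np.exp(1j * phi_tau)
    return PriorBundle(phi_tau=phi_tau, I_tau=I_tau, u_tau=u_tau, mode=mode,
                       upsample_factor=upsample_factor, pitch=pitch_tau,
                       wavelength=hologram.wavelength, z=z,
                       alpha_disabled=alpha_disabled)


def initialize(hologram: Hologram, prior: PriorBundle,
               gen_spec: GeneratorSpec, config: ADMMConfig) -> ADMMState:
    """Back-propagate I_tau for uo^0; t = 0; theta seeded random; k = 0."""
    holo_tau = Hologram(prior.I_tau, hologram.z2, hologram.wavelength,
                        prior.pitch)
    uo0 = backpropagate(holo_tau, prior.z).values
    params = gen.init_generator(gen_spec)
    kernel = _transfer_function(uo0.shape, prior.pitch,
                                prior.wavelength / 1e3, prior.z * UM_PER_MM)
    return ADMMState(uo=uo0, t=np.zeros_like(uo0), params=params,
                     gen_spec=gen_spec, kernel=kernel)


def hologram_fidelity(x2ch: Tensor, I_tau: np.ndarray,
                      kernel: np.ndarray) -> Tensor:
    """1/2 * || |propagate(u)|^2 - I_tau ||^2 as an autodiff node.

    ``x2ch`` holds (real, imag) channels of the object-plane field u; the
    propagation is the linear angular-spectrum map, and the gradient with
    respect to the channels is the Wirtinger gradient pulled back through
    the adjoint (conjugate-kernel) propagation.
    """
    u = _to_complex(x2ch.data)
    U = fft.ifft2(fft.fft2(u) * kernel)
    r = (U.real**2 + U.imag**2) - I_tau
    val = 0.5 * np.sum(r * r)

    def grad(g):
        dU = r * U   # dL/dU*
        du = fft.ifft2(fft.fft2(dU) * np.conj(kernel))
        return (g * 2.0 * np.stack([du.real, du.imag])).astype(x2ch.data.dtype)

    return Tensor(val, parents=((x2ch, grad),))


def _theta_objective(state: ADMMState, prior: PriorBundle,
                     config: ADMMConfig) -> tuple[Tensor, Tensor]:
    """Fidelity + proximity as a graph over theta; returns (loss, R node)."""
    x_in = Tensor(_to_2ch(state.uo))
    R = gen.forward(state.params, state.gen_spec, x_in)
    fid = hologram_fidelity(R, prior.I_tau, state.kernel)
    diff = Tensor(_to_2ch(state.uo - state.t)) - R
    prox = square_sum(diff) * (0.5 * config.beta)
    return fid + prox, R


def loss(params: dict[str, Tensor], uo: np.ndarray, t: np.ndarray,
         prior: PriorBundle, config: ADMMConfig, gen_spec: GeneratorSpec,
         kernel: np.ndarray) -> tuple[Tensor, dict[str, float]]:
    """Full objective with per-term breakdown; the returned Tensor
    backpropagates into the generator parameters."""
    x_in = Tensor(_to_2ch(uo))
    R = gen.forward(params, gen_spec, x_in)
    fid = hologram_fidelity(R, prior.I_tau, kernel)
    diff = Tensor(_to_2ch(uo - t)) - R
    prox = square_sum(diff) * (0.5 * config.beta)
    alpha = 0.0 if prior.alpha_disabled else config.alpha
    prior_term = 0.5 * alpha * float(np.real(np.vdot(uo, uo - prior.u_tau)))
    total = fid + prox + prior_term
    breakdown = {
        "fidelity": float(fid.data),
        "prior": prior_term,
        "proximity": float(prox.data),
        "total": float(fid.data + prox.data) + prior_term,
    }
    if not np.isfinite(breakdown["total"]):
        raise FloatingPointError(f"non-finite loss: {breakdown}")
    return total, breakdown


def update_theta(state: ADMMState, prior: PriorBundle,
                 config: ADMMConfig, optimizer: Adam | None = None) -> float:
    """Inner gradient steps on fidelity + proximity with uo, t frozen.

    Returns the sub-objective value after the update (evaluated with the
    refreshed network output, which is cached on the state for the
    subsequent object update).
    """
    if optimizer is None:
        optimizer = Adam(list(state.params.values()), lr=config.theta_lr)
    first = None
    for _ in range(config.inner_theta_steps):
        obj, _ = _theta_objective(state, prior, config)
        if first is None:
            first = float(obj.data)
        elif float(obj.data) > 10.0 * max(first, 1e-30):
            if state.lr_halvings >= 1:
                raise FloatingPointError(
                    f"theta update diverged at epoch {state.k} after lr halving")
            optimizer.lr *= 0.5
            state.lr_halvings += 1
            state.flags.append(f"theta divergence at epoch {state.k}: lr halved")
        optimizer.zero_grad()
        obj.backward()
        optimizer.step()
    # refresh the network output under the new parameters
    obj, R = _theta_objective(state, prior, config)
    state.R = _to_complex(R.data)
    return float(obj.data)


def update_object(state: ADMMState, prior: PriorBundle,
                  config: ADMMConfig) -> float:
    """Explicit steepest-descent step on uo with theta, t frozen.

    With the default c = 1/(alpha + beta) the step lands exactly on the
    minimizer (alpha*u_tau + beta*(R + t))/(alpha + beta) of the quadratic
    sub-problem.
    """
    if state.R is None:
        R = gen.forward(state.params, state.gen_spec, _to_2ch(state.uo))
        state.R = _to_complex(R.data)
    alpha = 0.0 if prior.alpha_disabled else config.alpha
    step = alpha * (state.uo - prior.u_tau) + config.beta * (
        state.uo - state.R - state.t)
    if np.linalg.norm(config.c * step) > np.linalg.norm(state.uo):
        state.flags.append(f"object step larger than field norm at epoch {state.k}")
    state.uo = state.uo - config.c * step
    prox = 0.5 * config.beta * float(np.sum(np.abs(state.uo - state.R - state.t) ** 2))
    prior_term = 0.5 * alpha * float(np.real(np.vdot(state.uo, state.uo - prior.u_tau)))
    return prior_term + prox


def update_multiplier(state: ADMMState, config: ADMMConfig) -> float:
    """Damped ADMM ascent on the splitting constraint uo = R_theta(uo) + t."""
    if config.multiplier_sign == "residual":
        state.t = state.t - config.multiplier_step * (state.uo - state.R)
    else:
        state.t = state.t - config.multiplier_step * (state.uo + state.R)
    return 0.5 * config.beta * float(
        np.sum(np.abs(state.uo - state.R - state.t) ** 2))


def check_convergence(residuals: tuple[float, float, float], tol: float,
                      n: int = 1) -> bool:
    """True when every normalized sub-objective drift is within tol/3."""
    eps = [abs(r) / n for r in residuals]
    return max(eps) <= tol / 3.0


def _readout(uo: np.ndarray, prior: PriorBundle) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude and unwrapped phase, referenced to the prior if present."""
    if prior.alpha_disabled:
        out = extract_amp_phase(
            ComplexField(uo, prior.pitch, prior.wavelength), unwrap=True)
        return out["amplitude"], out["phase"]
    phase = prior.phi_tau + np.angle(uo * np.exp(-1j * prior.phi_tau))
    phase = phase - border_mode(phase)
    return np.abs(uo), phase


def reconstruct(hologram: Hologram, mode: str, config: ADMMConfig | None = None,
                gen_spec: GeneratorSpec | None = None,
                prior_phase: np.ndarray | None = None,
                z: float | str = "auto", upsample_factor: int = 1) -> dict:
    """Run the full plug-and-play loop on one hologram.

    ``mode``: ``dip`` (no prior), ``dip-red`` (total-variation surrogate
    prior) or ``hybrid`` (file-based prior if ``prior_phase`` is given,
    otherwise bicubic surrogate).  Returns unwrapped phase and amplitude at
    the upsampled resolution plus a diagnostics dict (loss terms, residual
    history, stop reason, seeds, focused z).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    config = config or ADMMConfig()
    gen_spec = gen_spec or GeneratorSpec(seed=config.seed)
    if z == "auto":
        focus = autofocus(hologram, 0.6 * hologram.z2, 1.5 * hologram.z2)
        z_star = focus.z_star
    else:
        z_star = float(z)

    prior_mode = {"dip": "none", "dip-red": "tv",
                  "hybrid": "file" if prior_phase is not None else "bicubic"}[mode]
    prior = make_prior(hologram, prior_mode, upsample_factor, z_star,
                       prior_phase=prior_phase, tv_weight=config.tv_weight)
    state = initialize(hologram, prior, gen_spec, config)
    optimizer = Adam(list(state.params.values()), lr=config.theta_lr)

    n_pix = state.uo.size
    stop_reason = "max_epochs"
    tail: deque[np.ndarray] = deque(maxlen=max(config.avg_tail, 1))
    prev: tuple[float, float, float] | None = None
    for k in range(config.max_epochs):
        state.k = k
        l_theta = update_theta(state, prior, config, optimizer)
        l_uo = update_object(state, prior, config)
        l_t = update_multiplier(state, config)
        state.sub_objectives.append((l_theta, l_uo, l_t))
        tail.append(state.uo)
        # cheap per-epoch breakdown from the cached network output
        alpha = 0.0 if prior.alpha_disabled else config.alpha
        U = fft.ifft2(fft.fft2(state.R) * state.kernel)
        fid = 0.5 * float(np.sum(((U.real**2 + U.imag**2) - prior.I_tau) ** 2))
        prox = 0.5 * config.beta * float(
            np.sum(np.abs(state.uo - state.R - state.t) ** 2))
        prior_term = 0.5 * alpha * float(
            np.real(np.vdot(state.uo, state.uo - prior.u_tau)))
        breakdown = {"fidelity": fid, "prior": prior_term, "proximity": prox,
                     "total": fid + prox + prior_term}
        if not np.isfinite(breakdown["total"]):
            raise FloatingPointError(f"non-finite loss at epoch {k}: {breakdown}")
        state.loss_history.append(breakdown)
        if prev is not None:
            eps = tuple(abs(a - b) / n_pix
                        for a, b in zip((l_theta, l_uo, l_t), prev))
            state.residuals.append(eps)
            if check_convergence(eps, config.tol):
                stop_reason = "tolerance"
                state.k = k + 1
                break
        prev = (l_theta, l_uo, l_t)
    else:
        state.k = config.max_epochs

    uo_out = np.mean(tail, axis=0) if len(tail) > 1 else state.uo
    amplitude, phase = _readout(uo_out, prior)
    diagnostics = {
        "stop_reason": stop_reason,
        "epochs": state.k,
        "z_mm": z_star,
        "mode": mode,
        "prior_mode": prior_mode,
        "upsample_factor": upsample_factor,
        "seed": config.seed,
        "generator_seed": gen_spec.seed,
        "loss_history": state.loss_history,
        "residuals": [list(r) for r in state.residuals],
        "flags": state.flags,
    }
    return {"amplitude": amplitude, "phase": phase, "uo": uo_out,
            "diagnostics": diagnostics, "state": state, "prior": prior}
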