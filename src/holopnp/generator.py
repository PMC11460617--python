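"""The untrained generator network R_theta.

A small convolutional encoder-decoder with skip connections that maps a
two-channel (real, imaginary) representation of a complex field to a
refined two-channel field.  It is never pre-trained: its parameters are
fitted to a single measurement through the physics forward model, so the
architecture itself acts as the image prior (deep image prior).

Complex fields are channelized as (real, imaginary) rather than
(amplitude, phase): phase wrapping would put 2*pi discontinuities into an
otherwise smooth image and defeat the smoothness prior of the conv net.

Inputs whose height/width are not divisible by 2**depth are zero-padded
to the next multiple and cropped back after the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import (Tensor, avg_pool2, concat, conv2d, crop2d, leaky_relu,
                       pad2d, upsample_bilinear2)

__all__ = ["GeneratorSpec", "init_generator", "forward", "generate",
           "parameter_count", "save_params", "load_params", "param_checksum"]

_DTYPE = np.float32


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture hyperparameters of the encoder-decoder.

    ``depth`` down/up levels with ``base_channels`` features throughout,
    a ``skip_channels``-wide 1x1 skip at every level, LeakyReLU
    activations and bilinear upsampling.  Two channels in, two out.

    With ``residual`` (the default) the network computes x + f(x): it
    starts at the identity and learns a correction to its input.  This
    matters for strong-phase objects, whose complex field winds through
    several multiples of 2*pi — a generator that starts from random
    output would have to re-learn that winding from scratch, and any
    additive error larger than the local modulus tears it, which destroys
    the unwrapped phase.
    """

    depth: int = 3
    base_channels: int = 16
    skip_channels: int = 4
    activation: str = "leaky_relu"
    seed: int = 0
    residual: bool = True

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.activation != "leaky_relu":
            raise ValueError(f"unsupported activation {self.activation!r}")


def _layer_shapes(spec: GeneratorSpec) -> list[tuple[str, tuple, tuple]]:
    """(name, weight shape, bias shape) for every conv, in creation order."""
    b, s = spec.base_channels, spec.skip_channels
    shapes = []
    cin = 2
    for i in range(spec.depth):
        shapes.append((f"enc{i}", (b, cin, 3, 3), (b,)))
        shapes.append((f"skip{i}", (s, b, 1, 1), (s,)))
        cin = b
    shapes.append(("bottleneck", (b, b, 3, 3), (b,)))
    for i in reversed(range(spec.depth)):
        shapes.append((f"dec{i}", (b, b + s, 3, 3), (b,)))
    shapes.append(("head", (2, b, 1, 1), (2,)))
    return shapes


def parameter_count(spec: GeneratorSpec) -> int:
    return sum(int(np.prod(ws)) + int(np.prod(bs))
               for _, ws, bs in _layer_shapes(spec))


def init_generator(spec: GeneratorSpec) -> dict[str, Tensor]:
    """Fan-in-scaled (He) random initialization, fully determined by the seed."""
    rng = np.random.default_rng(spec.seed)
    params: dict[str, Tensor] = {}
    for name, wshape, bshape in _layer_shapes(spec):
        fan_in = int(np.prod(wshape[1:]))
        std = np.sqrt(2.0 / fan_in)
        if name == "head" and spec.residual:
            std = 1e-3   # start near the identity map
        params[f"{name}.w"] = Tensor(
            rng.normal(0.0, std, wshape).astype(_DTYPE), requires_grad=True)
        params[f"{name}.b"] = Tensor(np.zeros(bshape, dtype=_DTYPE),
                                     requires_grad=True)
    return params


def _check_finite(params: dict[str, Tensor]) -> None:
    for name, p in params.items():
        if not np.all(np.isfinite(p.data)):
            raise FloatingPointError(
                f"generator parameter {name} contains non-finite values "
                "(training diverged)")


def forward(params: dict[str, Tensor], spec: GeneratorSpec,
            x: Tensor | np.ndarray) -> Tensor:
    """Differentiable network forward pass: (2, H, W) -> (2, H, W)."""
    _check_finite(params)
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=_DTYPE))
    if x.data.ndim != 2 + 1 or x.data.shape[0] != 2:
        raise ValueError(f"expected (2, H, W) input, got {x.data.shape}")
    h0, w0 = x.data.shape[1:]
    m = 2 ** spec.depth
    pad_h = (-h0) % m
    pad_w = (-w0) % m
    h = pad2d(x, pad_h, pad_w) if (pad_h or pad_w) else x

    def conv(name: str, t: Tensor) -> Tensor:
        return conv2d(t, params[f"{name}.w"], params[f"{name}.b"])

    skips = []
    for i in range(spec.depth):
        h = leaky_relu(conv(f"enc{i}", h))
        skips.append(leaky_relu(conv(f"skip{i}", h)))
        h = avg_pool2(h)
    h = leaky_relu(conv("bottleneck", h))
    for i in reversed(range(spec.depth)):
        h = upsample_bilinear2(h)
        h = leaky_relu(conv(f"dec{i}", concat([h, skips[i]])))
    out = conv("head", h)
    if pad_h or pad_w:
        out = crop2d(out, h0, w0)
    if spec.residual:
        out = out + x
    return out


def generate(params: dict[str, Tensor], spec: GeneratorSpec,
             field_2ch: np.ndarray) -> np.ndarray:
    """Non-differentiating convenience wrapper around :func:`forward`."""
    return forward(params, spec, field_2ch).data


def param_checksum(params: dict[str, Tensor]) -> str:
    import hashlib

    h = hashlib.sha256()
    for name in sorted(params):
        h.update(name.encode())
        h.update(np.ascontiguousarray(params[name].data).tobytes())
    return h.hexdigest()


def save_params(path: str | Path, params: dict[str, Tensor],
                spec: GeneratorSpec) -> None:
    arrays = {name: p.data for name, p in params.items()}
    np.savez(Path(path), __spec__=np.array([repr(asdict(spec))]), **arrays)


def load_params(path: str | Path) -> tuple[dict[str, Tensor], GeneratorSpec]:
    import ast

    with np.load(Path(path), allow_pickle=False) as f:
        spec = GeneratorSpec(**ast.literal_eval(str(f["__spec__"][0])))
        params = {name: Tensor(f[name], requires_grad=True)
                  for name in f.files if name != "__spec__"}
    return params, spec
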