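"""Parameterised layers built on the autograd primitives.

Initialisation is He-style (ReLU gain) from a caller-supplied
``numpy.random.Generator`` so that two builds with the same seed are
bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(state)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for p{i}")
            p.data = arr


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class ConvNd(Module):
    """Same-padding stride-1 convolution (2D or 3D by kernel length)."""

    def __init__(self, c_in, c_out, kernel, rng, mask: np.ndarray | None = None):
        kernel = tuple(kernel)
        fan_in = c_in * int(np.prod(kernel))
        self.w = Tensor(_he(rng, (c_out, c_in) + kernel, fan_in), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self._mask = None
        if mask is not None:
            self._mask = np.broadcast_to(
                mask.astype(np.float32), self.w.data.shape
            ).copy()

    def __call__(self, x: Tensor) -> Tensor:
        w = self.w if self._mask is None else ag.mul_const(self.w, self._mask)
        return ag.conv_nd(x, w, self.b)


class MaskedConv2d(ConvNd):
    """3×3 convolution whose central tap is structurally zero (blind spot)."""

    def __init__(self, c_in, c_out, rng):
        mask = np.ones((3, 3), dtype=np.float32)
        mask[1, 1] = 0.0
        super().__init__(c_in, c_out, (3, 3), rng, mask=mask)


class UpConvNd(Module):
    """Transposed convolution with kernel == stride (block upsampling)."""

    def __init__(self, c_in, c_out, block, rng):
        block = tuple(block)
        self.w = Tensor(
            _he(rng, (c_in, c_out) + block, c_in), requires_grad=True
        )

    def __call__(self, x: Tensor) -> Tensor:
        return ag.upconv_nd(x, self.w)


class Linear(Module):
    def __init__(self, n_in, n_out, rng):
        self.w = Tensor(_he(rng, (n_in, n_out), n_in), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.w), self.b)
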