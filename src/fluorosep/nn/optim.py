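"""Adam optimiser (no weight decay, matching the training recipes)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        lr = np.float32(self.lr)  # keep parameters in float32 regardless of
        eps = np.float32(self.eps)  # the scalar types callers assign to lr
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = np.asarray(p.grad, dtype=np.float32)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / np.float32(b1t)
            vhat = self.v[i] / np.float32(b2t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + eps)
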