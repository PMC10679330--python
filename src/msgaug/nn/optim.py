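"""Gradient-descent optimizers (SGD with optional momentum, Adam)."""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE
from .layers import Parameter

__all__ = ["SGD", "Adam"]


class Optimizer:
    def __init__(self, params: list[Parameter], lr: float):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def load_state_arrays(self, state: dict[str, np.ndarray]):
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float, momentum: float = 0.0):
        super().__init__(params, lr)
        self.momentum = float(momentum)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        lr = DTYPE(self.lr)
        momentum = DTYPE(self.momentum)
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            if self.momentum:
                v *= momentum
                v += p.grad
                p.data = p.data - lr * v
            else:
                p.data = p.data - lr * p.grad

    def state_arrays(self):
        return {f"v{i}": v for i, v in enumerate(self._velocity)}

    def load_state_arrays(self, state):
        self._velocity = [state[f"v{i}"].astype(DTYPE) for i in range(len(self.params))]


class Adam(Optimizer):
    """Adam with configurable moment coefficients.

    The GAN training loop uses (beta1=0, beta2=0.99), the usual setting for
    multi-scale-gradient adversarial training; the defaults here are the
    generic Adam ones.
    """

    def __init__(self, params, lr: float, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2 = float(betas[0]), float(betas[1])
        self.eps = float(eps)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = DTYPE(self.beta1), DTYPE(self.beta2)
        bc1 = DTYPE(1.0 - self.beta1 ** self.t)
        bc2 = DTYPE(1.0 - self.beta2 ** self.t)
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data = p.data - DTYPE(self.lr) * (m / bc1) / (np.sqrt(v / bc2) + DTYPE(self.eps))

    def state_arrays(self):
        out = {"t": np.array(self.t)}
        for i, (m, v) in enumerate(zip(self._m, self._v)):
            out[f"m{i}"] = m
            out[f"v{i}"] = v
        return out

    def load_state_arrays(self, state):
        self.t = int(state["t"])
        n = len(self.params)
        self._m = [state[f"m{i}"].astype(DTYPE) for i in range(n)]
        self._v = [state[f"v{i}"].astype(DTYPE) for i in range(n)]
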