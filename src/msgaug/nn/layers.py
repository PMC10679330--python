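"""Neural-network building blocks on top of the autodiff engine.

Modules own :class:`Parameter` tensors, expose ``parameters()`` for the
optimizers, and carry a shared ``training`` flag (dropout is the only layer
that behaves differently at evaluation time).  Weight initialisation is
He-style and driven by an explicit ``numpy.random.Generator`` so that two
models built from the same seed have bitwise-identical parameters.
"""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Tensor, avg_pool2x, conv2d, upsample_nearest2x

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Dropout",
    "AvgPool2x",
    "UpsampleNearest2x",
    "Flatten",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module base: parameter collection and train/eval switching."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- flat state dict (numpy arrays), used by the checkpoint format ------
    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.state_arrays(prefix + name + "."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, p in self._params.items():
            src = state[prefix + k]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {prefix + k}: "
                                 f"{src.shape} vs {p.data.shape}")
            p.data = src.astype(DTYPE)
        for name, m in self._modules.items():
            m.load_state_arrays(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_scale(fan_in: int) -> float:
    return float(np.sqrt(2.0 / fan_in))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        w = rng.standard_normal((in_features, out_features)) * _he_scale(in_features)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.standard_normal(
            (out_channels, in_channels, kernel_size, kernel_size)) * _he_scale(fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels))
        # default: 'same' padding for odd kernels
        self.padding = kernel_size // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Dropout(Module):
    """Inverted dropout; identity in eval mode.

    The mask stream is owned by the module (seeded at construction) so that
    training runs are reproducible without threading an rng through forward.
    """

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self._rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


class AvgPool2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return avg_pool2x(x)


class UpsampleNearest2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest2x(x)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self._seq = list(modules)
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._seq:
            x = m(x)
        return x
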