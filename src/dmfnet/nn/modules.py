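"""Layer abstractions built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

_GLOBAL_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the generator used for parameter initialisation."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


def _rng(rng):
    return rng if rng is not None else _GLOBAL_RNG


class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {prefix + k: v.data for k, v in self._params.items()}
        state.update({prefix + k: v for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            state.update(m.named_state(prefix + name + "."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self._params.items():
            v.data = np.array(state[prefix + k], dtype=np.float64)
        for k in self._buffers:
            self._buffers[k] = np.array(state[prefix + k], dtype=np.float64)
        for name, m in self._modules.items():
            m.load_state(state, prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 zero_init: bool = False, rng=None):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        if zero_init:
            w = np.zeros((out_channels, in_channels, kernel_size, kernel_size))
        else:
            # He initialisation for ReLU networks
            w = _rng(rng).normal(
                0.0, np.sqrt(2.0 / fan_in),
                (out_channels, in_channels, kernel_size, kernel_size),
            )
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(num_features)
        self._buffers["running_var"] = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(-1)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(-1)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, -1, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class SGD:
    """Stochastic gradient descent with momentum and decoupled L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
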