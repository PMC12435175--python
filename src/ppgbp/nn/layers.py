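"""Neural-network layers built on the autodiff engine.

Layers follow a torch-like idiom: a :class:`Module` owns named
parameters and submodules, ``__call__`` maps Tensor -> Tensor, and
``state_dict``/``load_state_dict`` give flat numpy snapshots used for
best-epoch selection and on-disk checkpoints.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d, longconv_causal, maxpool1d

__all__ = [
    "Parameter", "Module", "Sequential", "Conv1d", "Linear", "BatchNorm1d",
    "ReLU", "MaxPool1d", "GlobalAvgPool1d", "Residual", "SSMLayer",
]


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: tracks parameters and submodules via attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    # ------------------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Non-trainable state (batch-norm running stats)."""
        out = {}
        for name, m in self._modules.items():
            out.update(m.buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- snapshots ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.named_parameters().items()}
        for k, b in self.buffers().items():
            out["buffer." + k] = b.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        for k, p in params.items():
            p.data[...] = state[k]
        bufs = self.buffers()
        for k in bufs:
            bufs[k][...] = state["buffer." + k]

    def __call__(self, x: Tensor) -> Tensor:
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def __call__(self, x: Tensor) -> Tensor:
        return x.relu()


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (c_in * kernel))  # He init for ReLU nets
        self.weight = Parameter(rng.normal(0.0, scale, size=(c_out, c_in, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = np.sqrt(1.0 / n_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Channel batch norm over (batch, time) with running statistics."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 zero_init: bool = False):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.zeros(c) if zero_init else np.ones(c))
        self.beta = Parameter(np.zeros(c))
        object.__setattr__(self, "running_mean", np.zeros(c, dtype=np.float32))
        object.__setattr__(self, "running_var", np.ones(c, dtype=np.float32))

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        return {prefix + "running_mean": self.running_mean,
                prefix + "running_var": self.running_var}

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2), keepdims=True)
            self.running_mean[...] = ((1 - self.momentum) * self.running_mean
                                      + self.momentum * mu.data.ravel())
            self.running_var[...] = ((1 - self.momentum) * self.running_var
                                     + self.momentum * var.data.ravel())
            norm = xc * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean[None, :, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None]
            norm = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return norm * g + b


class MaxPool1d(Module):
    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.k)


class GlobalAvgPool1d(Module):
    """(B, C, L) -> (B, C); the layer that makes input length flexible."""

    def __init__(self):
        super().__init__()

    def __call__(self, x: Tensor) -> Tensor:
        return x.mean(axis=2)


class Residual(Module):
    """y = relu(body(x) + shortcut(x)); identity shortcut by default."""

    def __init__(self, body: Module, shortcut: Module | None = None, final_relu: bool = True):
        super().__init__()
        self.body = body
        self.shortcut = shortcut
        self.final_relu = final_relu

    def __call__(self, x: Tensor) -> Tensor:
        s = x if self.shortcut is None else self.shortcut(x)
        y = self.body(x) + s
        return y.relu() if self.final_relu else y


class SSMLayer(Module):
    """Simplified diagonal state-space mixing layer.

    The state kernel is a learned linear combination of a fixed bank of
    damped cosines exp(-lambda_n t) cos(theta_n t) -- the impulse
    responses of a diagonal complex recurrence with log-spaced decay
    rates.  The combination weights (the state readout C) are trained;
    the spectrum itself is frozen, which keeps gradients simple while
    retaining long-range receptive fields.
    """

    def __init__(self, c: int, n_states: int = 8, kernel_len: int = 256,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        t = np.arange(kernel_len, dtype=np.float32)
        decays = np.geomspace(0.005, 0.2, n_states).astype(np.float32)
        thetas = np.linspace(0.0, np.pi / 4, n_states).astype(np.float32)
        basis = np.exp(-decays[:, None] * t[None, :]) * np.cos(thetas[:, None] * t[None, :])
        basis /= np.abs(basis).sum(axis=1, keepdims=True)  # unit-l1 rows
        object.__setattr__(self, "basis", basis.astype(np.float32))   # (n, K)
        self.mix = Parameter(rng.normal(0.0, 1.0 / np.sqrt(n_states), size=(c, n_states)))
        self.skip = Parameter(np.ones(c))
        self.norm = BatchNorm1d(c)

    def __call__(self, x: Tensor) -> Tensor:
        kern = self.mix @ Tensor(self.basis)          # (C, K)
        y = longconv_causal(x, kern) + x * self.skip.reshape(1, -1, 1)
        return self.norm(y).relu()
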