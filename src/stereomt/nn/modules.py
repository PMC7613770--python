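"""Layer containers built on the autodiff tensors.

Mirrors the familiar Module/Parameter idiom: submodules and parameters are
discovered through attribute assignment, ``state_dict`` flattens them under
dotted names, and ``train()``/``eval()`` toggle batch-norm behaviour.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor
from . import ops

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "ConvTranspose2d",
    "BatchNorm2d", "LeakyReLU", "ReLU", "Identity", "MaxPool2d",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    # -- traversal -----------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self, trainable_only: bool = True) -> int:
        return sum(int(p.size) for p in self.parameters()
                   if p.requires_grad or not trainable_only)

    # -- mode / grads --------------------------------------------------------

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ---------------------------------------------------

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state[name] = b.copy()
        return state

    def load_state_dict(self, state: dict, strict: bool = True):
        own_params = dict(self.named_parameters())
        own_buffers = dict(self.named_buffers())
        missing = (set(own_params) | set(own_buffers)) - set(state)
        unexpected = set(state) - set(own_params) - set(own_buffers)
        if strict and (missing or unexpected):
            raise KeyError(
                f"state dict mismatch: missing {sorted(missing)}, unexpected {sorted(unexpected)}"
            )
        for name, p in own_params.items():
            if name in state:
                if p.data.shape != state[name].shape:
                    raise ValueError(
                        f"shape mismatch for '{name}': {p.data.shape} vs {state[name].shape}"
                    )
                p.data[...] = state[name]
        for name, b in own_buffers.items():
            if name in state:
                b[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"_{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(shape, fan_in, rng, slope=0.1):
    gain = np.sqrt(2.0 / (1.0 + slope ** 2))
    std = gain / np.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


_init_rng = np.random.default_rng(0)


def seed_init(seed: int):
    """Reseed the generator used for fresh layer weights."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel=3, stride=1, padding=1, bias=True):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming((out_ch, in_ch, kernel, kernel), fan_in, _init_rng))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ops.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch, out_ch, kernel=4, stride=2, padding=1, bias=True):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel // (stride * stride)
        self.weight = Parameter(_kaiming((in_ch, out_ch, kernel, kernel), fan_in, _init_rng))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ops.conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_ch, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_ch, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_ch, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_ch))
        self.register_buffer("running_var", np.ones(num_ch))

    def forward(self, x):
        if self.training:
            out, mu, var = ops.batch_norm_train(x, self.weight, self.bias, self.eps)
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mu
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var
            return out
        # evaluation mode: normalize by the running statistics; the result
        # stays differentiable w.r.t. gamma/beta (and x) through the tape
        c = self.weight.data.shape[0]
        inv_sd = (1.0 / np.sqrt(self.running_var + self.eps)).astype(np.float32)
        xhat = (x - Tensor(self.running_mean.reshape(1, c, 1, 1))) \
            * Tensor(inv_sd.reshape(1, c, 1, 1))
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.1):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel=3, stride=2, padding=1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return ops.max_pool2d(x, self.kernel, self.stride, self.padding)
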