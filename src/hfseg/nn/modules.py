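"""Layer abstractions over the autodiff core.

Modules register parameters (trainable or frozen Tensors), buffers
(running statistics) and sub-modules through ``__setattr__``, and expose
named traversal, a train/eval switch and a flat ``state_dict``.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array: np.ndarray):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def trainable_parameters(self):
        return [p for p in self.parameters() if p.requires_grad]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, arr in d.items():
            if key in own:
                if own[key].data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for '{key}': model {own[key].data.shape}, "
                        f"checkpoint {arr.shape}")
                own[key].data = np.asarray(arr, dtype=np.float64).copy()
            elif key in bufs:
                if bufs[key].shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for buffer '{key}': model {bufs[key].shape}, "
                        f"checkpoint {arr.shape}")
                bufs[key][...] = arr
            else:
                raise KeyError(f"unexpected key in checkpoint: '{key}'")
        missing = (set(own) | set(bufs)) - set(d)
        if missing:
            raise KeyError(f"checkpoint missing keys: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Linear(Module):
    """y = x @ W.T + b with Xavier-uniform weight init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Tensor(rng.uniform(-bound, bound, (out_features, in_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.weight.shape[1]:
            raise ValueError(
                f"Linear: last axis is {x.shape[-1]}, expected {self.weight.shape[1]}")
        y = x @ self.weight.transpose(1, 0)
        return y + self.bias if self.bias is not None else y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: int = 0, dilation: int = 1, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.padding = padding
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias,
                        padding=self.padding, dilation=self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 2, bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Tensor(rng.normal(0.0, std, (in_ch, out_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.gamma, self.beta, self.eps)
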