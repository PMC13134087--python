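"""Neural-network building blocks on top of :mod:`lispcn.nn.tensor`."""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter registry, train/eval flag, state dicts."""

    def __init__(self) -> None:
        self._params: Dict[str, Tensor] = {}
        self._buffers: Dict[str, np.ndarray] = {}
        self._modules: Dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: Tensor) -> Tensor:
        value.requires_grad = True
        self._params[name] = value
        object.__setattr__(self, name, value)
        return value

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        object.__setattr__(self, name, value)
        return value

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name in self._buffers:
            # read through the attribute: modules may rebind the array
            yield prefix + name, getattr(self, name)
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        self.training = True
        for m in self._modules.values():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._modules.values():
            m.eval()
        return self

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.named_parameters()}
        for k, b in self.named_buffers():
            out[k] = np.asarray(b).copy()
        return out

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod = self
        *path, leaf = dotted.split(".")
        for part in path:
            mod = mod._modules[part]
        mod.register_buffer(leaf, value)

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(own) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing entries in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype).copy()
        for k, b in buffers.items():
            arr = np.asarray(state[k])
            if arr.shape != np.asarray(b).shape:
                raise ValueError(f"shape mismatch for buffer {k}")
            self._set_buffer(k, arr.astype(np.asarray(b).dtype).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 stride: int = 1, padding: int = 0,
                 rng: Optional[np.random.Generator] = None,
                 bias: bool = True) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init
        w = rng.normal(0.0, scale, (c_out, c_in, kernel, kernel))
        self.register_parameter("weight", Tensor(w.astype(np.float32)))
        if bias:
            self.register_parameter(
                "bias", Tensor(np.zeros(c_out, dtype=np.float32)))
        else:
            self.bias = None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int,
                 rng: Optional[np.random.Generator] = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        w = rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.register_parameter("weight", Tensor(w))
        self.register_parameter("bias", Tensor(np.zeros(n_out, dtype=np.float32)))

    def forward(self, x: Tensor) -> Tensor:
        return T.matmul(x, self.weight) + self.bias


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization with affine parameters."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.register_parameter(
            "gamma", Tensor(np.ones((1, channels, 1, 1), dtype=np.float32)))
        self.register_parameter(
            "beta", Tensor(np.zeros((1, channels, 1, 1), dtype=np.float32)))

    def forward(self, x: Tensor) -> Tensor:
        mu = T.mean(x, axis=(2, 3), keepdims=True)
        centred = x - mu
        var = T.mean(centred * centred, axis=(2, 3), keepdims=True)
        inv = T.power(var + self.eps, -0.5)
        return centred * inv * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return T.leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.tanh(x)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.upsample_nearest2x(x)


class Sequential(Module):
    def __init__(self, *mods: Module) -> None:
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0,
                    k_min: int = 3) -> int:
    """Adaptive 1-D kernel size for efficient channel attention.

    ``t = floor(log2(C)/gamma + b/gamma)``, rounded up to the nearest odd
    integer and floored at ``k_min`` so tiny channel widths still get a
    non-degenerate kernel.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    t = int(np.floor(np.log2(channels) / gamma + b / gamma))
    k = t if t % 2 == 1 else t + 1
    return max(k, k_min)


class ECA(Module):
    """Efficient channel attention: GAP -> 1-D conv over channels -> sigmoid gate."""

    def __init__(self, channels: int,
                 rng: Optional[np.random.Generator] = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k = eca_kernel_size(channels)
        # near-zero init: gates open at ~0.5 with live gradients, so the
        # sigmoid cannot saturate shut before training starts
        w = rng.normal(0.0, 0.01, (1, 1, 1, self.k))
        self.register_parameter("weight", Tensor(w.astype(np.float32)))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        desc = T.mean(x, axis=(2, 3))            # (n, c) channel descriptor
        seq = T.reshape(desc, (n, 1, 1, c))      # 1-D conv as a 1xk conv2d
        gate_logit = T.conv2d(seq, self.weight, None,
                              stride=1, padding=(0, self.k // 2))
        gate = T.sigmoid(T.reshape(gate_logit, (n, c, 1, 1)))
        return x * gate


class Adam:
    """Adam optimizer with externally adjustable learning rate."""

    def __init__(self, params: List[Tensor], lr: float,
                 beta1: float = 0.5, beta2: float = 0.99,
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                # decoupled (AdamW-style) decay
                p.data = p.data - self.lr * self.weight_decay * p.data

    def state_dict(self) -> Dict:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: Dict) -> None:
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]
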