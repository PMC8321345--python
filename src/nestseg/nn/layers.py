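"""Layer modules (convolution, batch norm) with explicit train/eval semantics.

Unlike most frameworks, the training/eval distinction is an explicit
``training`` argument to ``forward`` rather than ambient module state, so a
forward pass is fully determined by its arguments.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter/buffer registration and state-dict (de)serialization."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        p = Tensor(value, requires_grad=True)
        self._params[name] = p
        object.__setattr__(self, name, p)
        return p

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)
        return arr

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + n, b) for n, b in self._buffers.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_buffers(prefix + mn + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:") :]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: {p.data.shape} vs {value.shape}")
                p.data = value.astype(np.float32).copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU networks
        self.register_parameter("weight", rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        if bias:
            self.register_parameter("bias", np.zeros(out_ch))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.register_parameter("gamma", np.ones(n_ch))
        self.register_parameter("beta", np.zeros(n_ch))
        self.register_buffer("running_mean", np.zeros(n_ch))
        self.register_buffer("running_var", np.ones(n_ch))

    def forward(self, x: Tensor, training: bool) -> Tensor:
        return T.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training, self.momentum, self.eps)


class ConvBNReLU(Module):
    """3x3 (or other) convolution -> batch norm -> ReLU, the network's basic unit."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride=stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor, training: bool) -> Tensor:
        return T.relu(self.bn.forward(self.conv.forward(x), training))
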