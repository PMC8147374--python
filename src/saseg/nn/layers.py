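"""Network building blocks on top of the autograd engine.

Convolutions that are followed by batch normalization are bias-free (the
BN shift makes a bias redundant); only the final 1x1 output convolution
carries a bias.  Weight initialization is He-normal for conv kernels and
deterministic given the generator passed to ``init``.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "DSConv2d",
    "BatchNorm2d",
    "ReLU",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, Parameter):
                    state[f"{i}.{k}"] = v.data.copy()
                elif isinstance(v, np.ndarray):  # running BN stats
                    state[f"{i}.{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                key = f"{i}.{k}"
                if key in state:
                    if isinstance(v, Parameter):
                        v.data = state[key].astype(np.float32).copy()
                    elif isinstance(v, np.ndarray):
                        v[...] = state[key]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros((1, out_ch, 1, 1))) if bias else None
        self.stride = stride
        # "same"-size padding; even kernels pad asymmetrically (left/top short)
        total = kernel - stride if kernel >= stride else 0
        lo, hi = total // 2, total - total // 2
        self.pad = (lo, hi, lo, hi)

    def forward(self, x: Tensor) -> Tensor:
        out = x.conv2d(self.weight, stride=self.stride, pad=self.pad)
        if self.bias is not None:
            out = out + self.bias
        return out


class DSConv2d(Module):
    """Depthwise separable convolution: per-channel 3x3 then 1x1 fusion."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.depthwise = Parameter(rng.normal(0.0, np.sqrt(2.0 / 9), (in_ch, 3, 3)))
        self.pointwise = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / in_ch), (out_ch, in_ch, 1, 1))
        )

    def forward(self, x: Tensor) -> Tensor:
        return x.dwconv2d(self.depthwise).conv2d(self.pointwise, pad=(0, 0, 0, 0))


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.batchnorm(
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
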