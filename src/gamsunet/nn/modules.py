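"""Layer/module containers over the autodiff primitives."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class; parameters are discovered by attribute walk."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        self._collect(out, seen)
        return out

    def _collect(self, out: list, seen: set) -> None:
        def visit(v):
            if isinstance(v, Parameter):
                if id(v) not in seen:
                    seen.add(id(v))
                    out.append(v)
            elif isinstance(v, Module):
                v._collect(out, seen)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    visit(item)

        for v in vars(self).values():
            visit(v)

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []

        def visit(name, v):
            if isinstance(v, Parameter):
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    visit(f"{name}.{i}", item)

        for k, v in vars(self).items():
            visit(f"{prefix}{k}", v)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Conv2d(Module):
    """3x3/1x1 convolution with optional dilation; He init for leaky ReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        leaky_slope: float = 0.01,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        gain = np.sqrt(2.0 / (1.0 + leaky_slope**2))
        std = gain / np.sqrt(fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.padding = padding
        self.dilation = dilation
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(
            x, self.weight, self.bias, stride=1, padding=self.padding, dilation=self.dilation
        )


class GroupNorm(Module):
    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups:
            raise ValueError(f"{num_channels} channels not divisible by {num_groups} groups")
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))
        self.num_groups = num_groups
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ad.group_norm(x, self.gamma, self.beta, self.num_groups, self.eps)


class BatchNorm2dEval(Module):
    """Affine per-channel normalization as used by the reference nested U-Net.

    Only the parameter surface matters for architecture accounting (weight,
    bias, and non-trainable running statistics); forward normalizes with the
    running statistics, i.e. evaluation-mode batch norm, which is exact at
    batch size 1.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))
        self.running_mean = np.zeros(num_channels, dtype=np.float32)
        self.running_var = np.ones(num_channels, dtype=np.float32)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        c = x.data.shape[1]
        scale = (self.gamma.data / np.sqrt(self.running_var + self.eps)).reshape(1, c, 1, 1)
        shift = (self.beta.data - self.running_mean * scale.reshape(c)).reshape(1, c, 1, 1)
        return ad.add(ad.mul(x, Tensor(scale)), Tensor(shift))
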