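"""Convolutional building blocks shared by the baseline and improved detector.

The vocabulary: ``CBS`` (conv + batch norm + SiLU), the CSP-style ``C2f``
block with swappable inner residual units, ``SPPF`` (the baseline backbone
tail), partial convolution (``PConv``) and the ``FasterNetBlock`` built on
it.  All blocks preserve batch size, and spatial size at stride 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn import Tensor

__all__ = [
    "ConvSpec", "PartialConvSpec",
    "CBS", "Bottleneck", "C2f", "SPPF", "PConv", "FasterNetBlock",
    "count_parameters", "params_millions",
    "cbs_forward", "c2f_forward", "sppf_forward", "pconv_forward",
    "fasternet_block_forward",
]


@dataclass(frozen=True)
class ConvSpec:
    """Shape contract for a CBS layer; padding is always ``kernel // 2``."""

    c_in: int
    c_out: int
    kernel: int = 3
    stride: int = 1
    has_norm: bool = True
    activation: str = "silu"  # silu | relu | none

    def __post_init__(self):
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and positive, got {self.kernel}")
        if self.stride < 1:
            raise ValueError(f"stride must be positive, got {self.stride}")
        if self.activation not in ("silu", "relu", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class PartialConvSpec:
    """Partial 3x3 convolution: only the first ``c_partial`` channels convolve."""

    c_total: int
    partial_ratio: float = 0.25
    kernel: int = 3

    def __post_init__(self):
        if not (0.0 < self.partial_ratio <= 1.0):
            raise ValueError(f"partial_ratio must be in (0, 1], got {self.partial_ratio}")

    @property
    def c_partial(self) -> int:
        return max(1, round(self.c_total * self.partial_ratio))


class CBS(nn.Module):
    """Conv2d (no bias under norm) + BatchNorm + SiLU."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, activation="silu", has_norm=True):
        super().__init__()
        self.spec = ConvSpec(c_in, c_out, kernel, stride, has_norm, activation)
        self.conv = nn.Conv2d(c_in, c_out, kernel, stride=stride,
                              padding=kernel // 2, bias=not has_norm)
        self.norm = nn.BatchNorm2d(c_out) if has_norm else nn.Identity()
        self.act = {"silu": nn.SiLU, "relu": nn.ReLU, "none": nn.Identity}[activation]()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.c_in:
            raise ValueError(f"CBS expects {self.spec.c_in} channels, got {x.shape[1]}")
        return self.act(self.norm(self.conv(x)))


class Bottleneck(nn.Module):
    """Two 3x3 CBS layers with an optional residual sum (expansion 1.0)."""

    def __init__(self, channels, shortcut=True):
        super().__init__()
        self.cv1 = CBS(channels, channels, 3)
        self.cv2 = CBS(channels, channels, 3)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class PConv(nn.Module):
    """3x3 convolution over the first ``c_partial`` consecutive channels.

    The remaining channels pass through untouched (bit-identical); later
    pointwise layers let information flow across the full channel set.
    """

    def __init__(self, c_total, partial_ratio=0.25):
        super().__init__()
        self.spec = PartialConvSpec(c_total, partial_ratio)
        cp = self.spec.c_partial
        self.conv = nn.Conv2d(cp, cp, 3, stride=1, padding=1, bias=False)

    def forward(self, x):
        if x.shape[1] != self.spec.c_total:
            raise ValueError(f"PConv expects {self.spec.c_total} channels, got {x.shape[1]}")
        cp = self.spec.c_partial
        if cp == self.spec.c_total:
            return self.conv(x)
        return Tensor.cat([self.conv(x[:, :cp]), x[:, cp:]], axis=1)


class FasterNetBlock(nn.Module):
    """PConv followed by a pointwise MLP (expansion 2) and a skip connection.

    output = x + MLP(PConv(x)); the MLP is conv1x1 -> BN -> ReLU -> conv1x1,
    both pointwise convolutions bias-free.
    """

    def __init__(self, channels, partial_ratio=0.25, mlp_ratio=2):
        super().__init__()
        hidden = channels * mlp_ratio
        self.pconv = PConv(channels, partial_ratio)
        self.fc1 = nn.Conv2d(channels, hidden, 1, bias=False)
        self.norm = nn.BatchNorm2d(hidden)
        self.act = nn.ReLU()
        self.fc2 = nn.Conv2d(hidden, channels, 1, bias=False)

    def inner(self, x):
        return self.fc2(self.act(self.norm(self.fc1(self.pconv(x)))))

    def forward(self, x):
        return x + self.inner(x)


def _make_inner(kind: str, channels: int):
    if kind == "bottleneck":
        return Bottleneck(channels, shortcut=True)
    if kind == "fasternet":
        return FasterNetBlock(channels)
    if kind == "tbafn":
        from .attention import TBAFN  # deferred: attention builds on these blocks

        return TBAFN(channels)
    raise ValueError(f"unknown inner block kind {kind!r}")


class C2f(nn.Module):
    """CSP bottleneck with two 1x1 convolutions and ``n`` inner blocks.

    The 1x1 split/concat topology is fixed; the inner residual unit is
    swappable (classic bottleneck, FasterNet block, or TBAFN).
    """

    def __init__(self, c_in, c_out, n=1, shortcut=False, inner_block="bottleneck"):
        super().__init__()
        if n < 1:
            raise ValueError(f"C2f needs at least one inner block, got n={n}")
        self.c = c_out // 2
        self.cv1 = CBS(c_in, 2 * self.c, 1)
        self.cv2 = CBS((2 + n) * self.c, c_out, 1)
        inners = []
        for _ in range(n):
            m = _make_inner(inner_block, self.c)
            if inner_block == "bottleneck":
                m.shortcut = shortcut
            inners.append(m)
        self.m = nn.ModuleList(inners)

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, : self.c], y[:, self.c:]]
        for m in self.m:
            parts.append(m(parts[-1]))
        return self.cv2(Tensor.cat(parts, axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max-pools."""

    def __init__(self, c_in, c_out):
        super().__init__()
        hidden = c_in // 2
        self.cv1 = CBS(c_in, hidden, 1)
        self.cv2 = CBS(hidden * 4, c_out, 1)
        self.pool = nn.MaxPool2d(5, stride=1, padding=2)

    def forward(self, x):
        y0 = self.cv1(x)
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(Tensor.cat([y0, y1, y2, y3], axis=1))


def count_parameters(model: nn.Module) -> int:
    """Exact number of trainable scalars in ``model``."""
    return model.num_parameters()


def params_millions(model: nn.Module) -> float:
    """Parameter count in units of 10^6, rounded to two decimals."""
    return round(count_parameters(model) / 1e6, 2)


# -- thin functional wrappers (stateless entry points used in docs/tests) --

def cbs_forward(x: Tensor, spec: ConvSpec) -> Tensor:
    return CBS(spec.c_in, spec.c_out, spec.kernel, spec.stride,
               spec.activation, spec.has_norm)(x)


def c2f_forward(x: Tensor, n_inner: int, shortcut: bool = False,
                inner_block: str = "bottleneck") -> Tensor:
    c = x.shape[1]
    return C2f(c, c, n=n_inner, shortcut=shortcut, inner_block=inner_block)(x)


def sppf_forward(x: Tensor) -> Tensor:
    c = x.shape[1]
    return SPPF(c, c)(x)


def pconv_forward(x: Tensor, spec: PartialConvSpec) -> Tensor:
    return PConv(spec.c_total, spec.partial_ratio)(x)


def fasternet_block_forward(x: Tensor) -> Tensor:
    return FasterNetBlock(x.shape[1])(x)
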