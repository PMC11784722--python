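"""Attention blocks: IAIFI (transformer interaction + iterative fusion) and TBCAM.

IAIFI applies multi-head self-attention with 2-D sinusoidal positional
encoding to the deepest backbone map and fuses input and output through a
two-round iterative attentional feature fusion (iAFF) skip connection built
on multi-scale channel attention (MS-CAM).  TBCAM is a hybrid attention:
channel attention with alternating avg/max pooling, followed by three
permutation branches (HW, CH, CW) whose gated outputs are averaged.  TBAFN
embeds TBCAM inside a FasterNet block right before its residual addition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .core_blocks import CBS, FasterNetBlock
from .nn import Tensor

__all__ = [
    "PosEncodingSpec", "AttentionSpec",
    "sincos_position_encoding_2d", "MultiHeadSelfAttention",
    "multi_head_self_attention",
    "MSCAM", "mscam_attention", "IAFF", "iaff_fuse", "IAIFI", "iaifi_forward",
    "TBCAMChannelAttention", "tbcam_channel_attention",
    "TBCAMSpatialBranch", "tbcam_spatial_branch",
    "TBCAM", "tbcam_forward", "TBAFN", "tbafn_forward",
]


@dataclass(frozen=True)
class PosEncodingSpec:
    """Sinusoidal 2-D positional encoding: d/2 dims per axis, sin/cos pairs."""

    d: int
    T: float = 10000.0
    grid: tuple = (0, 0)  # (H, W) hint; encodings are built per call

    def __post_init__(self):
        if self.d % 4 != 0:
            raise ValueError(f"embedding dim must be divisible by 4, got {self.d}")
        if self.T <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class AttentionSpec:
    d_model: int
    n_heads: int

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError(f"d_model {self.d_model} not divisible by {self.n_heads} heads")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


def sincos_position_encoding_2d(H: int, W: int, spec: PosEncodingSpec) -> np.ndarray:
    """Absolute sin/cos encoding, one row per position, row-major over (y, x).

    Each row concatenates the d/2-dim encoding of the width index x and the
    d/2-dim encoding of the height index y; within each half, entry 2i is
    ``sin(pos / T^(2i/d))`` and entry 2i+1 the matching cosine.
    """
    d, T = spec.d, spec.T
    quarter = d // 4
    freqs = 1.0 / (T ** (2.0 * np.arange(quarter) / d))  # (d/4,)
    xs = np.arange(W, dtype=np.float64)
    ys = np.arange(H, dtype=np.float64)

    def encode(pos):  # (P,) -> (P, d/2) interleaved sin/cos
        ang = pos[:, None] * freqs[None, :]
        out = np.empty((pos.size, 2 * quarter))
        out[:, 0::2] = np.sin(ang)
        out[:, 1::2] = np.cos(ang)
        return out

    ex = encode(xs)  # (W, d/2)
    ey = encode(ys)  # (H, d/2)
    pe = np.empty((H * W, d), dtype=np.float32)
    pe[:, : d // 2] = np.tile(ex, (H, 1))
    pe[:, d // 2:] = np.repeat(ey, W, axis=0)
    return pe


class MultiHeadSelfAttention(nn.Module):
    """Self-attention over flattened spatial positions of a feature map.

    Q and K carry the positional encoding; V does not.  Input and output
    are NCHW feature maps with C == d_model.
    """

    def __init__(self, d_model: int, n_heads: int):
        super().__init__()
        self.spec = AttentionSpec(d_model, n_heads)
        self.in_proj = nn.Linear(d_model, 3 * d_model)
        self.out_proj = nn.Linear(d_model, d_model)

    def forward(self, x: Tensor, pe: np.ndarray | None = None) -> Tensor:
        n, c, h, w = x.shape
        d, nh = self.spec.d_model, self.spec.n_heads
        if c != d:
            raise ValueError(f"attention expects {d} channels, got {c}")
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, HW, d)
        if pe is not None:
            if pe.shape != (h * w, d):
                raise ValueError(f"positional encoding shape {pe.shape} != {(h * w, d)}")
            qk_in = tokens + Tensor(pe)
        else:
            qk_in = tokens
        dk = self.spec.d_k

        def heads(t):  # (N, HW, d) -> (N, nh, HW, dk)
            return t.reshape(n, h * w, nh, dk).transpose(0, 2, 1, 3)

        # project q/k from PE-augmented tokens, v from the raw tokens
        wq = self.in_proj.weight[:, :d]
        wk = self.in_proj.weight[:, d:2 * d]
        wv = self.in_proj.weight[:, 2 * d:]
        bq = self.in_proj.bias[:d]
        bk = self.in_proj.bias[d:2 * d]
        bv = self.in_proj.bias[2 * d:]
        q = heads(qk_in @ wq + bq)
        k = heads(qk_in @ wk + bk)
        v = heads(tokens @ wv + bv)
        attn = ((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dk))).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, h * w, d)
        out = self.out_proj(out)
        return out.transpose(0, 2, 1).reshape(n, c, h, w)


def multi_head_self_attention(x: Tensor, spec: AttentionSpec, pe: np.ndarray | None = None) -> Tensor:
    return MultiHeadSelfAttention(spec.d_model, spec.n_heads)(x, pe)


class _MSCAMBranch(nn.Module):
    def __init__(self, channels, reduction):
        super().__init__()
        inter = channels // reduction
        self.fc1 = nn.Conv2d(channels, inter, 1, bias=True)
        self.bn1 = nn.BatchNorm2d(inter)
        self.act = nn.ReLU()
        self.fc2 = nn.Conv2d(inter, channels, 1, bias=True)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x):
        return self.bn2(self.fc2(self.act(self.bn1(self.fc1(x)))))


class MSCAM(nn.Module):
    """Multi-scale channel attention: local per-position + global pooled branch."""

    def __init__(self, channels, reduction=4):
        super().__init__()
        if reduction >= channels:
            raise ValueError(f"reduction {reduction} must be < channels {channels}")
        self.local = _MSCAMBranch(channels, reduction)
        self.glob = _MSCAMBranch(channels, reduction)

    def forward(self, x: Tensor) -> Tensor:
        local = self.local(x)
        pooled = x.mean(axis=(2, 3), keepdims=True)
        glob = self.glob(pooled)
        return (local + glob).sigmoid()


def mscam_attention(x: Tensor, reduction: int = 4) -> Tensor:
    return MSCAM(x.shape[1], reduction)(x)


class IAFF(nn.Module):
    """Two-round iterative attentional feature fusion of branches X and Y.

    Round 1: a1 = MSCAM_1(X + Y), F1 = a1*X + (1-a1)*Y.
    Round 2: a2 = MSCAM_2(F1),    Z  = a2*X + (1-a2)*Y.
    Z is a pointwise convex combination of X and Y, so IAFF(X, X) == X.
    """

    def __init__(self, channels, reduction=4):
        super().__init__()
        self.att1 = MSCAM(channels, reduction)
        self.att2 = MSCAM(channels, reduction)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        if x.shape != y.shape:
            raise ValueError(f"fusion branches must share shape: {x.shape} vs {y.shape}")
        a1 = self.att1(x + y)
        fused = a1 * x + (1.0 - a1) * y
        a2 = self.att2(fused)
        return a2 * x + (1.0 - a2) * y


def iaff_fuse(X: Tensor, Y: Tensor, reduction: int = 4) -> Tensor:
    return IAFF(X.shape[1], reduction)(X, Y)


class IAIFI(nn.Module):
    """Intra-scale feature interaction with an iterative-fusion skip.

    A single post-norm transformer encoder layer (multi-head self-attention
    with 2-D sin/cos positional encoding on Q/K, then a pointwise
    feed-forward sublayer) is applied to the deepest feature map; the input
    and the encoded output are fused by iAFF instead of plain addition.
    Defaults (d_model=128 after the preceding 1x1 compression CBS, 8 heads,
    feed-forward dim 64, MS-CAM reduction 4) follow the published model-size
    budget of the composite detector.
    """

    def __init__(self, d_model=128, n_heads=8, ffn_dim=64, temperature=10000.0,
                 reduction=4):
        super().__init__()
        self.pe_spec = PosEncodingSpec(d_model, temperature)
        self.attn = MultiHeadSelfAttention(d_model, n_heads)
        self.norm1 = nn.LayerNorm(d_model)
        self.fc1 = nn.Linear(d_model, ffn_dim)
        self.act = nn.ReLU()
        self.fc2 = nn.Linear(ffn_dim, d_model)
        self.norm2 = nn.LayerNorm(d_model)
        self.fusion = IAFF(d_model, reduction)
        self._pe_cache: dict = {}

    def _pe(self, h, w):
        key = (h, w)
        if key not in self._pe_cache:
            self._pe_cache[key] = sincos_position_encoding_2d(h, w, self.pe_spec)
        return self._pe_cache[key]

    def encode(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        y = self.attn(x, self._pe(h, w))
        tokens = (x + y).reshape(n, c, h * w).transpose(0, 2, 1)
        tokens = self.norm1(tokens)
        ff = self.fc2(self.act(self.fc1(tokens)))
        tokens = self.norm2(tokens + ff)
        return tokens.transpose(0, 2, 1).reshape(n, c, h, w)

    def forward(self, x: Tensor) -> Tensor:
        return self.fusion(x, self.encode(x))


def iaifi_forward(x: Tensor) -> Tensor:
    return IAIFI(d_model=x.shape[1])(x)


class TBCAMChannelAttention(nn.Module):
    """Channel gate from alternating avg/max pooling over height and width.

    Two per-channel descriptors -- avg over H then max over W, and max over
    H then avg over W -- go through a shared bottleneck MLP; their sum is
    sigmoid-squashed into channel weights that rescale the input.
    """

    def __init__(self, channels, reduction=16):
        super().__init__()
        if reduction > channels:
            raise ValueError(f"reduction {reduction} exceeds channels {channels}")
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Conv2d(channels, hidden, 1, bias=False)
        self.act = nn.ReLU()
        self.fc2 = nn.Conv2d(hidden, channels, 1, bias=False)

    def _mlp(self, d):  # d: (N, C, 1, 1)
        return self.fc2(self.act(self.fc1(d)))

    def weights(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        d1 = x.mean(axis=2, keepdims=True).max(axis=3, keepdims=True)  # avg-H, max-W
        d2 = x.max(axis=2, keepdims=True).mean(axis=3, keepdims=True)  # max-H, avg-W
        return (self._mlp(d1) + self._mlp(d2)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.weights(x)


def tbcam_channel_attention(x: Tensor, reduction: int = 16) -> Tensor:
    return TBCAMChannelAttention(x.shape[1], reduction)(x)


_PERMUTATIONS = {
    # axes applied before the branch body; each is its own inverse
    "HW": (0, 1, 2, 3),  # gate over the HxW plane, stats across channels
    "CH": (0, 3, 2, 1),  # rotate so W takes the channel slot: (N, W, H, C)
    "CW": (0, 2, 1, 3),  # rotate so H takes the channel slot: (N, H, C, W)
}


class TBCAMSpatialBranch(nn.Module):
    """One permutation branch: concat(max, mean) -> 7x7 conv -> BN -> sigmoid gate."""

    def __init__(self, permutation: str = "HW"):
        super().__init__()
        if permutation not in _PERMUTATIONS:
            raise ValueError(f"permutation must be one of {sorted(_PERMUTATIONS)}")
        self.permutation = permutation
        self.conv = nn.Conv2d(2, 1, 7, padding=3, bias=False)
        self.bn = nn.BatchNorm2d(1)

    def forward(self, x: Tensor) -> Tensor:
        axes = _PERMUTATIONS[self.permutation]
        t = x.transpose(axes) if self.permutation != "HW" else x
        stats = Tensor.cat([t.max(axis=1, keepdims=True), t.mean(axis=1, keepdims=True)], axis=1)
        gate = self.bn(self.conv(stats)).sigmoid()
        out = t * gate
        return out.transpose(axes) if self.permutation != "HW" else out


def tbcam_spatial_branch(x: Tensor, permutation: str = "HW") -> Tensor:
    return TBCAMSpatialBranch(permutation)(x)


class TBCAM(nn.Module):
    """Three-branch convolution attention: channel gate, then averaged
    HW / CH / CW permutation branches."""

    def __init__(self, channels, reduction=16):
        super().__init__()
        self.channel = TBCAMChannelAttention(channels, reduction)
        self.branch_hw = TBCAMSpatialBranch("HW")
        self.branch_ch = TBCAMSpatialBranch("CH")
        self.branch_cw = TBCAMSpatialBranch("CW")

    def forward(self, x: Tensor) -> Tensor:
        xc = self.channel(x)
        return (self.branch_hw(xc) + self.branch_ch(xc) + self.branch_cw(xc)) * (1.0 / 3.0)


def tbcam_forward(x: Tensor, reduction: int = 16) -> Tensor:
    return TBCAM(x.shape[1], reduction)(x)


class TBAFN(nn.Module):
    """FasterNet block with TBCAM inserted before the residual addition:
    output = x + TBCAM(MLP(PConv(x)))."""

    def __init__(self, channels, partial_ratio=0.25, mlp_ratio=2, reduction=16):
        super().__init__()
        self.body = FasterNetBlock(channels, partial_ratio, mlp_ratio)
        self.tbcam = TBCAM(channels, reduction)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.tbcam(self.body.inner(x))


def tbafn_forward(x: Tensor) -> Tensor:
    return TBAFN(x.shape[1])(x)
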