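"""Detection head: adaptively spatial feature fusion and anchor-free decode.

The refactored head consumes a four-level pyramid (strides 4/8/16/32).  At
each output level the four maps are resampled to that level's geometry,
per-position fusion weights are produced by 1x1 compression convolutions
followed by a softmax across the level axis, and the weighted sum feeds a
decoupled classification/regression stem.  Box regression is
distribution-focal: each side is a ``reg_max``-bin distribution whose
expectation, scaled by the stride, gives the distance from the anchor
point to the box edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .core_blocks import CBS
from .nn import Tensor

__all__ = [
    "ScalePyramid", "Detection", "ASFFLevel", "DetectHead",
    "asff_weights", "asff_fuse", "decode_predictions", "box_iou_xyxy", "nms",
]


@dataclass
class ScalePyramid:
    """Ordered feature maps keyed by stride (4, 8, 16, 32)."""

    levels: dict

    def __post_init__(self):
        strides = sorted(self.levels)
        maps = [self.levels[s] for s in strides]
        for a, b, sa, sb in zip(maps, maps[1:], strides, strides[1:]):
            if sb != 2 * sa:
                raise ValueError(f"strides must double per level, got {strides}")
            if a.shape[2] != 2 * b.shape[2] or a.shape[3] != 2 * b.shape[3]:
                raise ValueError("spatial dims must halve per level")

    @property
    def strides(self):
        return sorted(self.levels)

    def maps(self):
        return [self.levels[s] for s in self.strides]


@dataclass
class Detection:
    """A scored box in absolute pixel xyxy coordinates."""

    box: tuple
    score: float
    class_id: int = 0

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate box {self.box}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


class ASFFLevel(nn.Module):
    """Adaptive fusion of the four pyramid levels into level ``l``.

    Every contributing scale (the native one included) is first projected
    into the level's channel space; coarser maps are 1x1-projected and
    nearest-upsampled, 2x finer maps downsampled by a 3x3 stride-2 CBS,
    and >=4x finer maps by a max-pool chain plus 1x1 projection.  The
    softmax-normalised weights are predicted per position from compressed
    (``compress`` channels) copies of the resampled maps.
    """

    def __init__(self, level: int, channels=(32, 64, 128, 256), compress=8):
        super().__init__()
        self.level = level
        self.channels = tuple(channels)
        cl = channels[level]
        resamplers = []
        for f, cf in enumerate(channels):
            if f == level:
                resamplers.append(CBS(cf, cl, 1))
            elif f > level:  # coarser, lower resolution: project then upsample
                resamplers.append(nn.Sequential(CBS(cf, cl, 1), nn.Upsample(2 ** (f - level))))
            else:            # finer, higher resolution: downsample
                k = level - f
                if k == 1:
                    resamplers.append(CBS(cf, cl, 3, stride=2))
                else:
                    pools = [nn.MaxPool2d(3, stride=2, padding=1) for _ in range(k)]
                    resamplers.append(nn.Sequential(*pools, CBS(cf, cl, 1)))
        self.resample = nn.ModuleList(resamplers)
        self.compress = nn.ModuleList([CBS(cl, compress, 1) for _ in channels])
        self.weight_conv = nn.Conv2d(compress * len(channels), len(channels), 1, bias=True)
        self.expand = CBS(cl, cl, 3)

    def resampled(self, pyramid_maps):
        return [r(m) for r, m in zip(self.resample, pyramid_maps)]

    def forward(self, pyramid_maps):
        maps = self.resampled(pyramid_maps)
        logits = self.weight_conv(Tensor.cat([c(m) for c, m in zip(self.compress, maps)], axis=1))
        w = asff_weights(logits)
        return self.expand(asff_fuse(maps, w))


def asff_weights(logits: Tensor) -> Tensor:
    """Softmax per-position fusion weights across the level axis (dim 1)."""
    return logits.softmax(axis=1)


def asff_fuse(maps, weights: Tensor) -> Tensor:
    """Per-position convex combination: sum_f w[:, f] * maps[f]."""
    n_levels = weights.shape[1]
    if len(maps) != n_levels:
        raise ValueError(f"{len(maps)} maps but {n_levels} weight slices")
    geo = maps[0].shape
    for m in maps:
        if m.shape != geo:
            raise ValueError("resampled maps must share geometry")
    out = maps[0] * weights[:, 0:1]
    for f in range(1, n_levels):
        out = out + maps[f] * weights[:, f:f + 1]
    return out


class DetectHead(nn.Module):
    """Decoupled anchor-free head: DFL box branch + class-logit branch."""

    def __init__(self, nc: int, ch: tuple, strides: tuple, reg_max: int = 16):
        super().__init__()
        self.nc, self.reg_max = nc, reg_max
        self.strides = tuple(strides)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = nn.ModuleList([
            nn.Sequential(CBS(c, c2, 3), CBS(c2, c2, 3),
                          nn.Conv2d(c2, 4 * reg_max, 1, bias=True))
            for c in ch
        ])
        self.cv3 = nn.ModuleList([
            nn.Sequential(CBS(c, c3, 3), CBS(c3, c3, 3),
                          nn.Conv2d(c3, nc, 1, bias=True))
            for c in ch
        ])
        self._init_biases()

    def _init_biases(self):
        # prior biases: near-unit box distances, low objectness (baseline convention)
        for reg, cls, s in zip(self.cv2, self.cv3, self.strides):
            reg[-1].bias.data[:] = 1.0
            cls[-1].bias.data[:] = math.log(5 / self.nc / (640 / s) ** 2)

    def forward(self, feats):
        if len(feats) != len(self.cv2):
            raise ValueError(f"expected {len(self.cv2)} levels, got {len(feats)}")
        return [Tensor.cat([self.cv2[i](f), self.cv3[i](f)], axis=1)
                for i, f in enumerate(feats)]


def box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (M,4) and (K,4) xyxy boxes."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list:
    """Greedy NMS; ties in score broken by original index (ascending)."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    keep = []
    suppressed = np.zeros(len(scores), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        if len(order) > 1:
            ious = box_iou_xyxy(boxes[i:i + 1], boxes)[0]
            suppressed |= ious > iou_thresh
            suppressed[i] = True
    return keep


def _level_grid(h, w, stride):
    xs = (np.arange(w) + 0.5) * stride
    ys = (np.arange(h) + 0.5) * stride
    gx, gy = np.meshgrid(xs, ys)
    return gx.ravel(), gy.ravel()


def decode_predictions(raw, strides, conf_thresh: float = 0.25,
                       iou_thresh: float = 0.45, nc: int = 1,
                       reg_max: int = 16) -> list:
    """Decode per-level raw maps into per-image lists of :class:`Detection`.

    Scores are sigmoid class probabilities; box sides come from the DFL bin
    expectation times the stride.  Greedy IoU NMS runs per class; surviving
    detections are ordered by descending score, then flat position index.
    """
    if not (0.0 <= conf_thresh <= 1.0 and 0.0 <= iou_thresh <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    batch = raw[0].shape[0]
    bins = np.arange(reg_max, dtype=np.float64)
    per_image = [[] for _ in range(batch)]
    boxes_all, scores_all, cls_all = [[] for _ in range(batch)], [[] for _ in range(batch)], [[] for _ in range(batch)]
    for lvl, s in zip(raw, strides):
        data = lvl.data if isinstance(lvl, Tensor) else np.asarray(lvl)
        n, c, h, w = data.shape
        reg = data[:, :4 * reg_max].reshape(n, 4, reg_max, h * w)
        cls = data[:, 4 * reg_max:4 * reg_max + nc].reshape(n, nc, h * w)
        ex = np.exp(reg - reg.max(axis=2, keepdims=True))
        dist = (ex / ex.sum(axis=2, keepdims=True) * bins[None, None, :, None]).sum(axis=2)  # (n,4,HW)
        gx, gy = _level_grid(h, w, s)
        x1 = gx[None] - dist[:, 0] * s
        y1 = gy[None] - dist[:, 1] * s
        x2 = gx[None] + dist[:, 2] * s
        y2 = gy[None] + dist[:, 3] * s
        score = 1.0 / (1.0 + np.exp(-np.clip(cls, -60, 60)))
        for b in range(n):
            conf = score[b].max(axis=0)
            cid = score[b].argmax(axis=0)
            m = conf >= conf_thresh
            if not m.any():
                continue
            boxes_all[b].append(np.stack([x1[b][m], y1[b][m], x2[b][m], y2[b][m]], axis=1))
            scores_all[b].append(conf[m])
            cls_all[b].append(cid[m])
    for b in range(batch):
        if not boxes_all[b]:
            continue
        boxes = np.concatenate(boxes_all[b])
        scores = np.concatenate(scores_all[b])
        cids = np.concatenate(cls_all[b])
        dets = []
        for c in np.unique(cids):
            sel = np.flatnonzero(cids == c)
            keep = nms(boxes[sel], scores[sel], iou_thresh)
            for i in keep:
                j = sel[i]
                x1_, y1_, x2_, y2_ = boxes[j]
                if x2_ <= x1_ or y2_ <= y1_:
                    continue  # degenerate at early training stages
                dets.append(Detection((float(x1_), float(y1_), float(x2_), float(y2_)),
                                      float(scores[j]), int(c)))
        dets.sort(key=lambda d: -d.score)
        per_image[b] = dets
    return per_image
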