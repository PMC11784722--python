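"""Declarative assembly of the baseline detector and its improved variants.

A :class:`ModelSpec` names one of the seven ablation configurations via
four independent flags:

``iaifi``
    replace the SPPF backbone tail with a 1x1 compression CBS plus the
    IAIFI transformer-interaction block;
``refactored_head``
    extend the neck to a stride-4 level and fuse all four scales with ASFF
    before a four-level decoupled head;
``fasternet``
    swap every C2f inner bottleneck for a FasterNet block;
``tbcam``
    further embed TBCAM in those FasterNet blocks (TBAFN) -- requires
    ``fasternet``.

Channel widths follow the nano multipliers (width 0.25, depth 0.33):
backbone ladder 16/32/64/128/256.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import nn
from .attention import IAIFI
from .core_blocks import C2f, CBS, SPPF, count_parameters, params_millions
from .head import ASFFLevel, DetectHead, ScalePyramid, decode_predictions
from .nn import Tensor

__all__ = ["ModelSpec", "DetectorNet", "build", "forward", "variant_table",
           "save_checkpoint", "load_checkpoint", "VARIANTS"]

VARIANTS = {
    "yolov8n":  dict(iaifi=False, refactored_head=False, fasternet=False, tbcam=False),
    "model1":   dict(iaifi=True,  refactored_head=False, fasternet=False, tbcam=False),
    "model2":   dict(iaifi=True,  refactored_head=True,  fasternet=False, tbcam=False),
    "model3":   dict(iaifi=True,  refactored_head=True,  fasternet=True,  tbcam=False),
    "model4":   dict(iaifi=False, refactored_head=True,  fasternet=True,  tbcam=True),
    "model5":   dict(iaifi=True,  refactored_head=False, fasternet=True,  tbcam=True),
    "imc_yolo": dict(iaifi=True,  refactored_head=True,  fasternet=True,  tbcam=True),
}


@dataclass
class ModelSpec:
    """Flag combination plus class count and expected input geometry."""

    iaifi: bool = False
    refactored_head: bool = False
    fasternet: bool = False
    tbcam: bool = False
    nc: int = 1
    input_size: tuple = (640, 640)
    reg_max: int = 16

    def __post_init__(self):
        if self.tbcam and not self.fasternet:
            raise ValueError("tbcam requires fasternet: TBCAM is embedded in the FasterNet block")
        if self.nc < 1:
            raise ValueError("need at least one class")
        h, w = self.input_size
        if h % 32 or w % 32:
            raise ValueError(f"input size must be divisible by 32, got {self.input_size}")

    @classmethod
    def from_variant(cls, variant: str, nc: int = 1, input_size=(640, 640)) -> "ModelSpec":
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
        return cls(nc=nc, input_size=tuple(input_size), **VARIANTS[variant])

    @property
    def variant(self) -> str:
        flags = dict(iaifi=self.iaifi, refactored_head=self.refactored_head,
                     fasternet=self.fasternet, tbcam=self.tbcam)
        for name, combo in VARIANTS.items():
            if combo == flags:
                return name
        return "custom"

    def to_yaml(self) -> str:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        d["variant"] = self.variant
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        d = yaml.safe_load(text)
        d.pop("variant", None)
        d["input_size"] = tuple(d.get("input_size", (640, 640)))
        return cls(**d)


class DetectorNet(nn.Module):
    """Executable network for any flag combination of :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        self.spec = spec
        inner = "tbafn" if spec.tbcam else ("fasternet" if spec.fasternet else "bottleneck")

        # backbone (stride 2..32); ladder 16/32/64/128/256
        self.stem = CBS(3, 16, 3, stride=2)
        self.down2 = CBS(16, 32, 3, stride=2)
        self.c2 = C2f(32, 32, n=1, shortcut=True, inner_block=inner)
        self.down3 = CBS(32, 64, 3, stride=2)
        self.c3 = C2f(64, 64, n=2, shortcut=True, inner_block=inner)
        self.down4 = CBS(64, 128, 3, stride=2)
        self.c4 = C2f(128, 128, n=2, shortcut=True, inner_block=inner)
        self.down5 = CBS(128, 256, 3, stride=2)
        self.c5 = C2f(256, 256, n=1, shortcut=True, inner_block=inner)
        if spec.iaifi:
            self.tail = nn.Sequential(CBS(256, 128, 1), IAIFI(d_model=128))
            p5ch = 128
        else:
            self.tail = SPPF(256, 256)
            p5ch = 256
        self.p5ch = p5ch

        # FPN up path
        self.up = nn.Upsample(2)
        self.n_p4 = C2f(p5ch + 128, 128, n=1, inner_block=inner)
        self.n_p3 = C2f(128 + 64, 64, n=1, inner_block=inner)

        if spec.refactored_head:
            self.n_p2 = C2f(64 + 32, 32, n=1, inner_block=inner)
            self.d_p3 = CBS(32, 32, 3, stride=2)
            self.m_p3 = C2f(32 + 64, 64, n=1, inner_block=inner)
            self.d_p4 = CBS(64, 64, 3, stride=2)
            self.m_p4 = C2f(64 + 128, 128, n=1, inner_block=inner)
            self.d_p5 = CBS(128, 128, 3, stride=2)
            self.m_p5 = C2f(128 + p5ch, 256, n=1, inner_block=inner)
            ch = (32, 64, 128, 256)
            self.level_strides = (4, 8, 16, 32)
            self.asff = nn.ModuleList([ASFFLevel(l, ch) for l in range(4)])
        else:
            self.d_p4 = CBS(64, 64, 3, stride=2)
            self.m_p4 = C2f(64 + 128, 128, n=1, inner_block=inner)
            self.d_p5 = CBS(128, 128, 3, stride=2)
            self.m_p5 = C2f(128 + p5ch, 256, n=1, inner_block=inner)
            ch = (64, 128, 256)
            self.level_strides = (8, 16, 32)
            self.asff = None
        self.detect = DetectHead(spec.nc, ch, self.level_strides, reg_max=spec.reg_max)

    # -- execution --------------------------------------------------------
    def pyramid(self, images: Tensor) -> ScalePyramid:
        """Run backbone + neck; return the fused per-stride feature maps."""
        if images.shape[2] % 32 or images.shape[3] % 32:
            raise ValueError(f"input H/W must be divisible by 32, got {images.shape[2:]}")
        x = self.down2(self.stem(images))
        f2 = self.c2(x)                      # stride 4
        f3 = self.c3(self.down3(f2))         # stride 8
        f4 = self.c4(self.down4(f3))         # stride 16
        f5 = self.tail(self.c5(self.down5(f4)))  # stride 32

        u4 = self.n_p4(Tensor.cat([self.up(f5), f4], axis=1))
        u3 = self.n_p3(Tensor.cat([self.up(u4), f3], axis=1))
        if self.spec.refactored_head:
            p2 = self.n_p2(Tensor.cat([self.up(u3), f2], axis=1))
            p3 = self.m_p3(Tensor.cat([self.d_p3(p2), u3], axis=1))
            p4 = self.m_p4(Tensor.cat([self.d_p4(p3), u4], axis=1))
            p5 = self.m_p5(Tensor.cat([self.d_p5(p4), f5], axis=1))
            levels = dict(zip((4, 8, 16, 32), (p2, p3, p4, p5)))
        else:
            p4 = self.m_p4(Tensor.cat([self.d_p4(u3), u4], axis=1))
            p5 = self.m_p5(Tensor.cat([self.d_p5(p4), f5], axis=1))
            levels = dict(zip((8, 16, 32), (u3, p4, p5)))
        return ScalePyramid(levels)

    def forward(self, images: Tensor):
        pyr = self.pyramid(images)
        maps = pyr.maps()
        if self.asff is not None:
            maps = [lvl(maps) for lvl in self.asff]
        return self.detect(maps)

    def predict(self, images: Tensor, conf_thresh=0.25, iou_thresh=0.45):
        self.eval()
        with nn.no_grad():
            raw = self.forward(images)
        return decode_predictions(raw, self.level_strides, conf_thresh, iou_thresh,
                                  nc=self.spec.nc, reg_max=self.spec.reg_max)


def build(spec: ModelSpec | str, seed: int = 0, nc: int = 1) -> DetectorNet:
    """Construct a network; ``seed`` fixes the parameter initialization."""
    if isinstance(spec, str):
        spec = ModelSpec.from_variant(spec, nc=nc)
    nn.seed_all(seed)
    return DetectorNet(spec)


def forward(network: DetectorNet, images: Tensor):
    return network(images)


def variant_table(nc: int = 1) -> list:
    """Build all seven ablation variants and report their sizes."""
    rows = []
    for name, flags in VARIANTS.items():
        net = build(name, nc=nc)
        rows.append({"model": name, **flags,
                     "params": count_parameters(net),
                     "params_millions": params_millions(net)})
    return rows


def save_checkpoint(net: DetectorNet, path) -> None:
    """Weights as npz next to a JSON sidecar holding the model config."""
    path = str(path)
    state = net.state_dict()
    np.savez_compressed(path, **state)
    cfg = asdict(net.spec)
    cfg["input_size"] = list(cfg["input_size"])
    with open(path + ".json", "w") as fh:
        json.dump(cfg, fh)


def load_checkpoint(path) -> DetectorNet:
    path = str(path)
    with open(path + ".json") as fh:
        cfg = json.load(fh)
    cfg["input_size"] = tuple(cfg["input_size"])
    net = DetectorNet(ModelSpec(**cfg))
    archive = np.load(path if path.endswith(".npz") else path + ".npz")
    net.load_state_dict({k: archive[k] for k in archive.files})
    return net
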