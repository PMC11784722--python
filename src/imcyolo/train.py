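"""Training harness: config, batch assembly, optimization loop, logging."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import model_zoo
from .datakit import DatasetIndex, annotations_to_xyxy
from .evalkit import evaluate
from .head import Detection
from .losses import detection_loss
from .model_zoo import DetectorNet
from .nn import Adam, Tensor, linear_lr

__all__ = ["RunConfig", "Trainer", "load_image_batch", "evaluate_network"]


@dataclass
class RunConfig:
    """Training hyperparameters (published defaults)."""

    epochs: int = 100
    batch_size: int = 16
    input_size: tuple = (640, 640)
    optimizer: str = "adam"
    lr0: float = 0.001
    lr_final_factor: float = 0.01
    seed: int = 0
    variant: str = "imc_yolo"
    nc: int = 1
    conf_thresh_eval: float = 0.001
    nms_iou_eval: float = 0.7

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str)
                              .encode()).hexdigest()[:12]


def load_image_batch(paths, size=None):
    """Load images into a (N, 3, H, W) float tensor scaled to [0, 1]."""
    arrays = []
    for p in paths:
        img = Image.open(p).convert("RGB")
        if size is not None and img.size != (size[1], size[0]):
            img = img.resize((size[1], size[0]), Image.BILINEAR)
        arrays.append(np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0)
    return Tensor(np.stack(arrays))


def _targets_from_records(records, hw):
    h, w = hw
    targets = []
    for r in records:
        boxes = annotations_to_xyxy(r.annotations, w, h)
        labels = np.array([a.class_id for a in r.annotations], dtype=np.int64)
        targets.append({"boxes": boxes, "labels": labels})
    return targets


class Trainer:
    """Plain SGD-era loop: linear LR decay, JSONL logging, npz checkpoints."""

    def __init__(self, net: DetectorNet, config: RunConfig, log_path=None):
        self.net = net
        self.config = config
        self.opt = Adam(net.parameters(), lr=config.lr0)
        self.log_path = Path(log_path) if log_path else None
        self.history = []

    def _log(self, entry: dict):
        entry["config"] = self.config.digest()
        self.history.append(entry)
        if self.log_path:
            with open(self.log_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")

    def train_steps(self, images: Tensor, targets, n_steps: int,
                    lr_schedule: bool = True, log_every: int = 25):
        """Optimize on one fixed batch for ``n_steps``; returns loss trace."""
        self.net.train()
        trace = []
        for step in range(n_steps):
            if lr_schedule:
                self.opt.lr = linear_lr(self.config.lr0, self.config.lr_final_factor,
                                        step, n_steps)
            loss, parts = detection_loss(self.net(images), self.net.level_strides,
                                         targets, nc=self.config.nc)
            self.opt.zero_grad()
            loss.backward()
            self.opt.step()
            trace.append(parts)
            if log_every and step % log_every == 0:
                self._log({"step": step, "lr": self.opt.lr, **parts})
        return trace

    def fit(self, index: DatasetIndex, epochs=None, checkpoint_path=None):
        """Epoch loop over the train split of a materialized dataset."""
        cfg = self.config
        epochs = epochs or cfg.epochs
        records = index.by_split("train")
        if not records:
            raise ValueError("dataset has no train records")
        rng = np.random.default_rng(cfg.seed)
        total_steps = epochs * max(len(records) // cfg.batch_size, 1)
        step = 0
        for epoch in range(epochs):
            order = rng.permutation(len(records))
            epoch_losses = []
            for start in range(0, len(records) - cfg.batch_size + 1, cfg.batch_size):
                batch = [records[i] for i in order[start:start + cfg.batch_size]]
                images = load_image_batch([r.image_path for r in batch], cfg.input_size)
                targets = _targets_from_records(batch, cfg.input_size)
                self.opt.lr = linear_lr(cfg.lr0, cfg.lr_final_factor, step, total_steps)
                loss, parts = detection_loss(self.net(images), self.net.level_strides,
                                             targets, nc=cfg.nc)
                self.opt.zero_grad()
                loss.backward()
                self.opt.step()
                epoch_losses.append(parts["total"])
                step += 1
            self._log({"epoch": epoch, "loss": float(np.mean(epoch_losses)),
                       "lr": self.opt.lr, "time": time.time()})
            if checkpoint_path:
                model_zoo.save_checkpoint(self.net, checkpoint_path)
        return self.history


def evaluate_network(net: DetectorNet, index: DatasetIndex, split="val",
                     input_size=None, conf_thresh=0.001, nms_iou=0.7,
                     batch_size=8):
    """Run inference over a split and score it with the metric stack."""
    from .evalkit import GroundTruthBox

    records = index.by_split(split) if split else list(index.records)
    if not records:
        raise ValueError(f"no records in split {split!r}")
    size = input_size
    dets_all, gts_all = [], []
    for start in range(0, len(records), batch_size):
        batch = records[start:start + batch_size]
        images = load_image_batch([r.image_path for r in batch], size)
        h, w = images.shape[2], images.shape[3]
        dets = net.predict(images, conf_thresh=conf_thresh, iou_thresh=nms_iou)
        dets_all.extend(dets)
        for r in batch:
            boxes = annotations_to_xyxy(r.annotations, w, h)
            gts_all.append([GroundTruthBox(tuple(b), a.class_id)
                            for b, a in zip(boxes, r.annotations)])
    return evaluate(dets_all, gts_all), dets_all, gts_all
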