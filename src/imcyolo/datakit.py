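"""Dataset handling: labels, splits, augmentation protocol, synthetic scenes.

Labels use the normalized YOLO text convention (``class cx cy w h`` per
line).  The augmentation protocol mirrors a field-collected burrow corpus:
each original image spawns a brighter copy (+40% per channel), a darker one
(-40%), a salt-and-pepper corrupted one (corruption probability 0.5) and a
horizontal flip, and augmented copies always inherit their source image's
train/val/test split so no information leaks across splits.

Because the real mudflat corpus is not public, :func:`generate_scene`
synthesises stand-in scenes: procedurally textured mud with many small dark
soft-edged elliptical burrows whose relative box sizes concentrate in the
small-object regime.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "Annotation", "ImageRecord", "DatasetIndex", "SceneParams",
    "read_yolo_labels", "write_yolo_labels", "parse_yolo_labels",
    "split_dataset", "adjust_brightness", "salt_pepper_noise", "hflip",
    "expand_with_augmentations", "generate_scene", "generate_dataset",
    "load_manifest", "annotations_to_xyxy",
]

AUGMENTATIONS = ("bright+", "bright-", "saltpepper", "hflip")
SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class Annotation:
    """One normalized box: center/extent fractions of the image."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box extent must be positive")
        if self.class_id < 0:
            raise ValueError("class_id must be nonnegative")


def parse_yolo_labels(text: str) -> list:
    """Parse label text; raises ``ValueError`` naming the offending line."""
    out = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ValueError(f"line {ln}: expected 5 fields, got {len(fields)}")
        try:
            cid = int(fields[0])
            vals = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise ValueError(f"line {ln}: {exc}") from None
        try:
            out.append(Annotation(cid, *vals))
        except ValueError as exc:
            raise ValueError(f"line {ln}: {exc}") from None
    return out


def read_yolo_labels(path) -> list:
    return parse_yolo_labels(Path(path).read_text())


def write_yolo_labels(annotations, path) -> None:
    lines = [f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}"
             for a in annotations]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def annotations_to_xyxy(annotations, width: int, height: int) -> np.ndarray:
    """Normalized (cx, cy, w, h) -> absolute pixel xyxy array (K, 4)."""
    if not annotations:
        return np.zeros((0, 4))
    arr = np.array([[a.cx, a.cy, a.w, a.h] for a in annotations], dtype=np.float64)
    scale = np.array([width, height, width, height])
    cxywh = arr * scale
    return np.stack([cxywh[:, 0] - cxywh[:, 2] / 2, cxywh[:, 1] - cxywh[:, 3] / 2,
                     cxywh[:, 0] + cxywh[:, 2] / 2, cxywh[:, 1] + cxywh[:, 3] / 2], axis=1)


@dataclass
class ImageRecord:
    image_path: str
    annotations: list
    split: str
    provenance: str = "original"
    source: str | None = None  # image_path of the original this was derived from

    def __post_init__(self):
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")
        if self.provenance != "original" and self.provenance not in AUGMENTATIONS:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class DatasetIndex:
    records: list = field(default_factory=list)
    class_names: list = field(default_factory=lambda: ["burrow"])

    @property
    def expanded(self) -> bool:
        return any(r.provenance != "original" for r in self.records)

    def by_split(self, split: str) -> list:
        return [r for r in self.records if r.split == split]

    def leakage_pairs(self) -> list:
        """(source, derived) pairs whose split assignments disagree."""
        split_of = {r.image_path: r.split for r in self.records if r.provenance == "original"}
        return [(r.source, r.image_path) for r in self.records
                if r.source is not None and split_of.get(r.source) != r.split]


def split_dataset(n_items: int, ratios=(0.7, 0.15, 0.15), seed: int = 0) -> list:
    """Random split assignment with largest-remainder rounding.

    Returns a list of split names, one per item.  Counts are the exact
    quotas ``n * ratio`` rounded by largest remainder (ties resolved in
    train/val/test order), shuffled deterministically under ``seed``.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    quotas = [n_items * r for r in ratios]
    counts = [int(math.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    short = n_items - sum(counts)
    for i in sorted(range(len(ratios)), key=lambda i: (-remainders[i], i))[:short]:
        counts[i] += 1
    labels = np.repeat(np.array(SPLITS, dtype=object), counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return list(labels)


def adjust_brightness(img: np.ndarray, factor: float) -> np.ndarray:
    """Scale every channel by (1 + factor); round half away from zero, clip."""
    if abs(factor) >= 1:
        raise ValueError(f"|factor| must be < 1, got {factor}")
    scaled = img.astype(np.float64) * (1.0 + factor)
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def salt_pepper_noise(img: np.ndarray, intensity: float = 0.5, seed: int = 0,
                      per_channel: bool = False) -> np.ndarray:
    """Corrupt each pixel to pure black/white with probability ``intensity``."""
    if not (0.0 <= intensity <= 1.0):
        raise ValueError(f"intensity must be in [0, 1], got {intensity}")
    rng = np.random.default_rng(seed)
    out = img.copy()
    if per_channel:
        hit = rng.random(img.shape) < intensity
        val = rng.random(img.shape) < 0.5
        out[hit] = np.where(val[hit], 255, 0)
    else:
        hit = rng.random(img.shape[:2]) < intensity
        val = (rng.random(img.shape[:2]) < 0.5)
        out[hit] = np.where(val[hit, None], 255, 0)
    return out


def hflip(img: np.ndarray, annotations) -> tuple:
    """Mirror on the width axis; box centers map cx -> 1 - cx."""
    flipped = img[:, ::-1].copy()
    anns = [replace(a, cx=1.0 - a.cx) for a in annotations]
    return flipped, anns


def expand_with_augmentations(index: DatasetIndex, seed: int = 0) -> DatasetIndex:
    """Spawn the four augmented records per original (5x total records).

    Augmented records inherit their source's split (leakage isolation);
    salt-and-pepper keeps the source labels, the horizontal flip transforms
    them.  The returned index carries provenance; image pixels are
    materialized separately (:func:`generate_dataset` or the CLI).
    """
    if index.expanded:
        raise ValueError("index already holds augmented records")
    out = DatasetIndex(records=list(index.records), class_names=list(index.class_names))
    for rec in index.records:
        stem = Path(rec.image_path)
        for prov in AUGMENTATIONS:
            suffix = {"bright+": "brightp", "bright-": "brightm",
                      "saltpepper": "sp", "hflip": "hflip"}[prov]
            anns = rec.annotations
            if prov == "hflip":
                anns = [replace(a, cx=1.0 - a.cx) for a in anns]
            out.records.append(ImageRecord(
                image_path=str(stem.with_name(f"{stem.stem}_{suffix}{stem.suffix}")),
                annotations=list(anns), split=rec.split, provenance=prov,
                source=rec.image_path))
    return out


@dataclass
class SceneParams:
    """Knobs of the synthetic mudflat generator.

    Defaults emulate the field corpus: 640px frames, 5-15 burrows per frame
    of 6-20px radius, so nearly all boxes fall well below 1% of the image
    area (the small-object regime that makes the task hard).
    """

    size: tuple = (640, 640)  # (H, W)
    n_burrows: tuple = (5, 15)
    radius: tuple = (6.0, 20.0)
    eccentricity: tuple = (0.55, 1.0)
    texture_scale: int = 16    # coarse-noise cell size in px
    illumination: float = 1.0  # global brightness multiplier
    seed: int = 0

    def __post_init__(self):
        if self.n_burrows[0] < 0 or self.n_burrows[1] < self.n_burrows[0]:
            raise ValueError("invalid burrow count range")
        if self.radius[0] <= 0 or self.radius[1] < self.radius[0]:
            raise ValueError("invalid radius range")
        if 2 * self.radius[1] >= min(self.size):
            raise ValueError("burrows must fit inside the image")


def _mud_background(h, w, rng, scale, illumination):
    base = np.array([148.0, 125.0, 100.0]) * illumination  # wet-sediment brown
    ch, cw = max(h // scale, 2), max(w // scale, 2)
    coarse = rng.normal(0, 18, (ch, cw))
    reps = (math.ceil(h / ch), math.ceil(w / cw))
    coarse = np.kron(coarse, np.ones(reps))[:h, :w]
    # cheap smoothing of the block artifacts
    coarse = (coarse + np.roll(coarse, scale // 2, 0) + np.roll(coarse, scale // 2, 1)) / 3.0
    speckle = rng.normal(0, 7, (h, w))
    lum = coarse + speckle
    img = base[None, None, :] + lum[:, :, None] * np.array([1.0, 0.95, 0.85])
    return img


def _place_burrows(h, w, k, rng, params):
    placed = []
    attempts = 0
    while len(placed) < k and attempts < 40 * max(k, 1):
        attempts += 1
        a = rng.uniform(*params.radius)                 # semi-major axis
        b = a * rng.uniform(*params.eccentricity)       # semi-minor axis
        theta = rng.uniform(0, math.pi)
        ct, st = math.cos(theta), math.sin(theta)
        half_w = math.sqrt((a * ct) ** 2 + (b * st) ** 2)
        half_h = math.sqrt((a * st) ** 2 + (b * ct) ** 2)
        if 2 * half_w >= w - 2 or 2 * half_h >= h - 2:
            continue
        cx = rng.uniform(half_w + 1, w - half_w - 1)
        cy = rng.uniform(half_h + 1, h - half_h - 1)
        if any((cx - px) ** 2 + (cy - py) ** 2 < (0.8 * (a + pa)) ** 2
               for px, py, pa, *_ in placed):
            continue
        placed.append((cx, cy, a, b, theta, half_w, half_h))
    return placed


def generate_scene(params: SceneParams):
    """One synthetic mudflat frame plus exact normalized box annotations.

    Deterministic under ``params.seed``.  Burrows are dark soft-edged
    ellipses with a faint displaced rim highlight; the emitted box is the
    axis-aligned extent of each ellipse.  If placement retries run out the
    scene simply holds fewer burrows.
    """
    h, w = params.size
    rng = np.random.default_rng(params.seed)
    img = _mud_background(h, w, rng, params.texture_scale, params.illumination)
    k = int(rng.integers(params.n_burrows[0], params.n_burrows[1] + 1))
    burrows = _place_burrows(h, w, k, rng, params)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    annotations = []
    for cx, cy, a, b, theta, half_w, half_h in burrows:
        ct, st = math.cos(theta), math.sin(theta)
        x0, y0 = xx - cx, yy - cy
        u = (x0 * ct + y0 * st) / a
        v = (-x0 * st + y0 * ct) / b
        rho = np.sqrt(u * u + v * v)
        # smooth dark well: full depth inside, soft shoulder to 1.0 at the edge
        depth = np.clip((1.0 - rho) / 0.25, 0.0, 1.0)
        darken = 1.0 - 0.78 * depth ** 1.5
        rim = 1.0 + 0.12 * np.exp(-((rho - 1.06) / 0.1) ** 2)
        img *= (darken * rim)[:, :, None]
        annotations.append(Annotation(
            0, cx / w, cy / h, 2 * half_w / w, 2 * half_h / h))
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, annotations


def generate_dataset(out_dir, n_images: int, params: SceneParams | None = None,
                     seed: int = 0, augment: bool = False,
                     ratios=(0.7, 0.15, 0.15)) -> DatasetIndex:
    """Write a synthetic corpus (PNG + YOLO labels + manifest) to disk."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    params = params or SceneParams()
    splits = split_dataset(n_images, ratios, seed=seed)
    index = DatasetIndex()
    for i in range(n_images):
        img, anns = generate_scene(replace(params, seed=seed * 100003 + i))
        ipath = out / "images" / f"scene_{i:04d}.png"
        Image.fromarray(img).save(ipath)
        write_yolo_labels(anns, out / "labels" / f"scene_{i:04d}.txt")
        index.records.append(ImageRecord(str(ipath), anns, splits[i]))
    if augment:
        index = expand_with_augmentations(index, seed=seed)
        for rec in index.records:
            if rec.provenance == "original":
                continue
            src = np.asarray(Image.open(rec.source).convert("RGB"))
            if rec.provenance == "bright+":
                img = adjust_brightness(src, +0.40)
            elif rec.provenance == "bright-":
                img = adjust_brightness(src, -0.40)
            elif rec.provenance == "saltpepper":
                tag = zlib.crc32(Path(rec.image_path).name.encode()) & 0x7FFFFFFF
                img = salt_pepper_noise(src, 0.5, seed=seed ^ tag)
            else:
                img, _ = hflip(src, [])
            Image.fromarray(img).save(rec.image_path)
            lpath = out / "labels" / (Path(rec.image_path).stem + ".txt")
            write_yolo_labels(rec.annotations, lpath)
    _write_manifest(out, index)
    return index


def _write_manifest(out: Path, index: DatasetIndex) -> None:
    manifest = {
        "path": str(out),
        "names": index.class_names,
        "records": [
            {"image": str(Path(r.image_path).relative_to(out)),
             "label": f"labels/{Path(r.image_path).stem}.txt",
             "split": r.split, "provenance": r.provenance,
             "source": (str(Path(r.source).relative_to(out)) if r.source else None)}
            for r in index.records
        ],
    }
    (out / "dataset.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def load_manifest(path) -> DatasetIndex:
    """Rebuild a :class:`DatasetIndex` from a ``dataset.yaml`` manifest."""
    path = Path(path)
    if path.is_dir():
        path = path / "dataset.yaml"
    if not path.exists():
        raise FileNotFoundError(f"dataset manifest not found: {path}")
    data = yaml.safe_load(path.read_text())
    root = path.parent
    index = DatasetIndex(class_names=list(data.get("names", ["burrow"])))
    for r in data["records"]:
        anns = read_yolo_labels(root / r["label"])
        index.records.append(ImageRecord(
            str(root / r["image"]), anns, r["split"], r.get("provenance", "original"),
            str(root / r["source"]) if r.get("source") else None))
    return index
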