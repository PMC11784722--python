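"""Detection training loss: task-aligned assignment + BCE + CIoU + DFL.

The architecture work changes the network, not the objective, so the loss
keeps the anchor-free baseline recipe: a task-aligned assigner picks the
positive anchor points per ground-truth box (alignment metric
``score^alpha * IoU^beta``), classification is binary cross-entropy
against the normalized alignment scores, and box regression combines a
complete-IoU term with distribution-focal loss over the discretized side
distances.  Assignment runs on detached values; gradients flow through
the class logits and the box/distribution heads only.
"""

from __future__ import annotations

import numpy as np

from .head import box_iou_xyxy
from .nn import Tensor

__all__ = ["make_anchors", "task_aligned_assign", "detection_loss"]


def make_anchors(shapes, strides):
    """Anchor-point centers (pixels) and per-anchor stride for all levels."""
    pts, strs = [], []
    for (h, w), s in zip(shapes, strides):
        xs = (np.arange(w) + 0.5) * s
        ys = (np.arange(h) + 0.5) * s
        gx, gy = np.meshgrid(xs, ys)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
        strs.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(pts), np.concatenate(strs)


def _ciou(pred: Tensor, target: np.ndarray) -> Tensor:
    """Complete IoU between predicted boxes (M,4 tensor) and targets (M,4)."""
    tx1, ty1, tx2, ty2 = target[:, 0], target[:, 1], target[:, 2], target[:, 3]
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    pw = (px2 - px1).clamp(lo=1e-6)
    ph = (py2 - py1).clamp(lo=1e-6)
    tw = np.maximum(tx2 - tx1, 1e-6)
    th = np.maximum(ty2 - ty1, 1e-6)

    ix1 = Tensor.cat([px1.reshape(-1, 1), Tensor(tx1).reshape(-1, 1)], axis=1).max(axis=1)
    iy1 = Tensor.cat([py1.reshape(-1, 1), Tensor(ty1).reshape(-1, 1)], axis=1).max(axis=1)
    ix2 = (-Tensor.cat([(-px2).reshape(-1, 1), Tensor(-tx2).reshape(-1, 1)], axis=1).max(axis=1))
    iy2 = (-Tensor.cat([(-py2).reshape(-1, 1), Tensor(-ty2).reshape(-1, 1)], axis=1).max(axis=1))
    iw = (ix2 - ix1).clamp(lo=0.0)
    ih = (iy2 - iy1).clamp(lo=0.0)
    inter = iw * ih
    union = pw * ph + tw * th - inter
    iou = inter / (union + 1e-9)

    # enclosing box diagonal and center distance
    cx1 = -Tensor.cat([(-px1).reshape(-1, 1), Tensor(-tx1).reshape(-1, 1)], axis=1).max(axis=1)
    cy1 = -Tensor.cat([(-py1).reshape(-1, 1), Tensor(-ty1).reshape(-1, 1)], axis=1).max(axis=1)
    cx2 = Tensor.cat([px2.reshape(-1, 1), Tensor(tx2).reshape(-1, 1)], axis=1).max(axis=1)
    cy2 = Tensor.cat([py2.reshape(-1, 1), Tensor(ty2).reshape(-1, 1)], axis=1).max(axis=1)
    c2 = (cx2 - cx1) ** 2 + (cy2 - cy1) ** 2 + 1e-9
    rho2 = ((px1 + px2 - tx1 - tx2) * 0.5) ** 2 + ((py1 + py2 - ty1 - ty2) * 0.5) ** 2

    v = ((Tensor(np.arctan(tw / th)) - (pw / ph).atan()) ** 2) * (4.0 / np.pi ** 2)
    alpha = v.data / np.maximum(1.0 - iou.data + v.data, 1e-9)  # detached
    return iou - rho2 / c2 - v * alpha


def task_aligned_assign(scores: np.ndarray, boxes: np.ndarray,
                        anchors: np.ndarray, gt_boxes: np.ndarray,
                        gt_labels: np.ndarray, topk: int = 10,
                        alpha: float = 0.5, beta: float = 6.0):
    """Assign anchors of one image to ground-truth boxes.

    Returns (target_boxes (A,4), target_scores (A,nc), fg_mask (A,)).
    Candidates are anchors whose center lies inside the box; the ``topk``
    by ``score^alpha * IoU^beta`` per box become positives, each anchor
    keeping only its highest-IoU box.  Target class scores are the
    alignment metrics normalized per box to peak at that box's best IoU.
    """
    A, nc = scores.shape
    tgt_boxes = np.zeros((A, 4))
    tgt_scores = np.zeros((A, nc))
    fg = np.zeros(A, dtype=bool)
    if len(gt_boxes) == 0:
        return tgt_boxes, tgt_scores, fg
    inside = ((anchors[:, 0:1] > gt_boxes[None, :, 0]) & (anchors[:, 0:1] < gt_boxes[None, :, 2]) &
              (anchors[:, 1:2] > gt_boxes[None, :, 1]) & (anchors[:, 1:2] < gt_boxes[None, :, 3]))
    ious = box_iou_xyxy(boxes, gt_boxes)  # (A, G)
    cls_score = scores[:, gt_labels]      # (A, G)
    align = (np.clip(cls_score, 1e-9, 1) ** alpha) * (ious ** beta) * inside
    G = gt_boxes.shape[0]
    mask = np.zeros((A, G), dtype=bool)
    k = min(topk, A)
    top_idx = np.argsort(-align, axis=0)[:k]  # (k, G)
    for g in range(G):
        sel = top_idx[:, g]
        sel = sel[align[sel, g] > 0]
        mask[sel, g] = True
    # an anchor serving several boxes keeps the one it overlaps most
    multi = mask.sum(axis=1) > 1
    if multi.any():
        best = np.argmax(np.where(mask, ious, -1.0), axis=1)
        mask[multi] = False
        mask[np.flatnonzero(multi), best[multi]] = True
    fg = mask.any(axis=1)
    assigned = np.argmax(mask, axis=1)
    # per-box normalization of the alignment metric
    pos_align = np.where(mask, align, 0.0)
    pos_iou = np.where(mask, ious, 0.0)
    norm = pos_iou.max(axis=0) / np.maximum(pos_align.max(axis=0), 1e-9)
    for a in np.flatnonzero(fg):
        g = assigned[a]
        tgt_boxes[a] = gt_boxes[g]
        tgt_scores[a, gt_labels[g]] = align[a, g] * norm[g]
    return tgt_boxes, tgt_scores, fg


def detection_loss(raw_levels, strides, targets, nc: int = 1, reg_max: int = 16,
                   box_gain: float = 7.5, cls_gain: float = 0.5, dfl_gain: float = 1.5):
    """Total loss for a batch.

    ``raw_levels``: per-level (N, 4*reg_max + nc, H, W) prediction tensors.
    ``targets``: per-image dict with ``boxes`` (G,4 pixel xyxy) and
    ``labels`` (G,).  Returns (loss, parts dict of floats).
    """
    N = raw_levels[0].shape[0]
    shapes = [(t.shape[2], t.shape[3]) for t in raw_levels]
    anchors, stride_t = make_anchors(shapes, strides)
    A = anchors.shape[0]

    flat = Tensor.cat(
        [t.reshape(N, t.shape[1], t.shape[2] * t.shape[3]) for t in raw_levels], axis=2
    ).transpose(0, 2, 1)  # (N, A, 4*reg_max + nc)
    dist_logits = flat[:, :, :4 * reg_max].reshape(N, A, 4, reg_max)
    cls_logits = flat[:, :, 4 * reg_max:]

    bins = np.arange(reg_max, dtype=np.float32)
    prob = dist_logits.softmax(axis=-1)
    dist = (prob * Tensor(bins)).sum(axis=-1)  # (N, A, 4) in stride units
    sgrid = Tensor(stride_t.astype(np.float32).reshape(1, A, 1))
    ax = anchors[:, 0].astype(np.float32)
    ay = anchors[:, 1].astype(np.float32)
    dpx = dist * sgrid
    x1 = Tensor(ax.reshape(1, A)) - dpx[:, :, 0]
    y1 = Tensor(ay.reshape(1, A)) - dpx[:, :, 1]
    x2 = Tensor(ax.reshape(1, A)) + dpx[:, :, 2]
    y2 = Tensor(ay.reshape(1, A)) + dpx[:, :, 3]

    with_np = lambda t: t.data  # detached views for the assigner
    pred_scores_np = 1.0 / (1.0 + np.exp(-np.clip(with_np(cls_logits), -60, 60)))
    boxes_np = np.stack([with_np(x1), with_np(y1), with_np(x2), with_np(y2)], axis=-1)

    tgt_scores = np.zeros((N, A, nc), dtype=np.float32)
    tgt_boxes = np.zeros((N, A, 4), dtype=np.float32)
    fg = np.zeros((N, A), dtype=bool)
    for b in range(N):
        gtb = np.asarray(targets[b]["boxes"], dtype=np.float64).reshape(-1, 4)
        gtl = np.asarray(targets[b]["labels"], dtype=np.int64).reshape(-1)
        tb, ts, m = task_aligned_assign(pred_scores_np[b], boxes_np[b], anchors, gtb, gtl)
        tgt_boxes[b], tgt_scores[b], fg[b] = tb, ts, m

    score_sum = max(float(tgt_scores.sum()), 1.0)

    # classification: BCE with logits against the soft alignment targets
    z = cls_logits
    t = Tensor(tgt_scores)
    zpos = z.clamp(lo=0.0)
    zabs = zpos + (-z).clamp(lo=0.0)
    bce = zpos - z * t + ((-zabs).exp() + 1.0).log()
    loss_cls = bce.sum() * (1.0 / score_sum)

    parts = {}
    if fg.any():
        bidx, aidx = np.nonzero(fg)
        pred_pos = Tensor.cat([
            x1[bidx, aidx].reshape(-1, 1), y1[bidx, aidx].reshape(-1, 1),
            x2[bidx, aidx].reshape(-1, 1), y2[bidx, aidx].reshape(-1, 1)], axis=1)
        tboxes = tgt_boxes[bidx, aidx]
        weight = tgt_scores[bidx, aidx].sum(axis=1).astype(np.float32)
        ciou = _ciou(pred_pos, tboxes)
        loss_box = ((1.0 - ciou) * Tensor(weight)).sum() * (1.0 / score_sum)

        # DFL: cross-entropy on the two bins flanking the true distance
        s_pos = stride_t[aidx].astype(np.float32)
        tdist = np.stack([
            anchors[aidx, 0] - tboxes[:, 0], anchors[aidx, 1] - tboxes[:, 1],
            tboxes[:, 2] - anchors[aidx, 0], tboxes[:, 3] - anchors[aidx, 1]], axis=1)
        tdist = np.clip(tdist / s_pos[:, None], 0.0, reg_max - 1 - 1e-3).astype(np.float32)
        tl = np.floor(tdist)
        wr = tdist - tl
        wl = 1.0 - wr
        logits_pos = dist_logits[bidx, aidx]  # (M, 4, reg_max)
        shift = logits_pos.data.max(axis=-1, keepdims=True)
        logp = logits_pos - Tensor(shift) - ((logits_pos - Tensor(shift)).exp().sum(axis=-1, keepdims=True)).log()
        onehot_l = np.eye(reg_max, dtype=np.float32)[tl.astype(int)]
        onehot_r = np.eye(reg_max, dtype=np.float32)[np.minimum(tl + 1, reg_max - 1).astype(int)]
        ce = -(logp * Tensor(onehot_l * wl[..., None] + onehot_r * wr[..., None])).sum(axis=-1)
        loss_dfl = (ce.mean(axis=1) * Tensor(weight)).sum() * (1.0 / score_sum)
    else:
        loss_box = Tensor(np.zeros(()))
        loss_dfl = Tensor(np.zeros(()))

    total = loss_box * box_gain + loss_cls * cls_gain + loss_dfl * dfl_gain
    parts.update(box=float(loss_box.data), cls=float(loss_cls.data),
                 dfl=float(loss_dfl.data), total=float(total.data),
                 n_pos=int(fg.sum()))
    return total, parts
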