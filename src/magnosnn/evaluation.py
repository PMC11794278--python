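"""Spike-time MAE and detection-style metrics for motion maps.

MAE is the mean absolute difference between output and label spike times
across neurons.  For detection metrics, thresholded motion maps are turned
into scored boxes (connected components, 4-connectivity), matched greedily
against ground truth in descending score order at an IoU threshold (default
0.25 — appropriate for low-resolution frames with few pixels per target),
and summarized as precision, recall and average precision.  AP uses all-point
interpolation (the area under the precision envelope of the PR curve); boxes
are half-open pixel rectangles (x, y, w, h) with 0-based top-left origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectionBox",
    "EvalReport",
    "mae",
    "precision_recall",
    "box_iou",
    "match_detections",
    "match_and_ap",
    "motionmap_to_boxes",
]

#: 4-connectivity structuring element for component labeling
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class DetectionBox:
    """Half-open pixel box with a confidence score in [0, 1]."""

    x: int
    y: int
    w: int
    h: int
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive extent, got w={self.w}, h={self.h}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def xywh(self) -> tuple[int, int, int, int]:
        return (self.x, self.y, self.w, self.h)


@dataclass(frozen=True)
class EvalReport:
    mae: float
    precision: float
    recall: float
    ap: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def mae(out_times: np.ndarray, label_times: np.ndarray) -> float:
    """Mean absolute spike-time error ``(1/N) sum |T_i - T_hat_i|``."""
    out_times = np.asarray(out_times, dtype=float)
    label_times = np.asarray(label_times, dtype=float)
    if out_times.shape != label_times.shape:
        raise ValueError(f"length mismatch: {out_times.shape} vs {label_times.shape}")
    if out_times.size == 0:
        raise ValueError("need at least one neuron")
    return float(np.mean(np.abs(out_times - label_times)))


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN).

    An undefined ratio (zero denominator) is reported as nan rather than 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return precision, recall


def box_iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    """IoU of two half-open (x, y, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("boxes must have positive extent")
    ix = max(0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def _gt_boxes_per_frame(gt) -> list[np.ndarray]:
    """Accept a GroundTruth object or a per-frame sequence of (n, 4) arrays."""
    boxes = getattr(gt, "boxes", gt)
    return [np.atleast_2d(np.asarray(b, dtype=np.int64)).reshape(-1, 4) for b in boxes]


def match_detections(
    detections: Sequence[Sequence[DetectionBox]],
    gt,
    iou_threshold: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Greedy score-descending matching, one detection per ground-truth box.

    Returns (scores, is_tp) over all detections in descending-score order
    (ties broken by ascending input index) and the total ground-truth count.
    A detection is a true positive when its best IoU against a still-unmatched
    ground-truth box of the same frame strictly exceeds the threshold.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    gt_frames = _gt_boxes_per_frame(gt)
    if len(detections) != len(gt_frames):
        raise ValueError(
            f"detections cover {len(detections)} frames but ground truth {len(gt_frames)}")
    flat = [(det.score, idx, frame_idx, det)
            for idx, (frame_idx, det) in enumerate(
                (f, d) for f, frame in enumerate(detections) for d in frame)]
    flat.sort(key=lambda item: (-item[0], item[1]))
    matched = [np.zeros(len(g), dtype=bool) for g in gt_frames]
    n_gt = int(sum(len(g) for g in gt_frames))
    scores = np.array([item[0] for item in flat], dtype=float)
    is_tp = np.zeros(len(flat), dtype=bool)
    for rank, (_, _, frame_idx, det) in enumerate(flat):
        candidates = gt_frames[frame_idx]
        best_iou, best_j = 0.0, -1
        for j, box in enumerate(candidates):
            if matched[frame_idx][j]:
                continue
            iou = box_iou(det.xywh, tuple(box))
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou > iou_threshold:
            matched[frame_idx][best_j] = True
            is_tp[rank] = True
    return scores, is_tp, n_gt


def _ap_from_matches(is_tp: np.ndarray, n_gt: int) -> float:
    if n_gt == 0:
        return float("nan")
    if is_tp.size == 0:
        return 0.0
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(~is_tp)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # all-point interpolation: area under the precision envelope
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * envelope))


def match_and_ap(
    detections: Sequence[Sequence[DetectionBox]],
    gt,
    iou_threshold: float = 0.25,
) -> float:
    """Average precision of per-frame detections against ground truth."""
    _, is_tp, n_gt = match_detections(detections, gt, iou_threshold)
    return _ap_from_matches(is_tp, n_gt)


def evaluate_detections(
    detections: Sequence[Sequence[DetectionBox]],
    gt,
    iou_threshold: float = 0.25,
    spike_mae: float = float("nan"),
) -> EvalReport:
    """Full report: precision/recall over all detections plus AP."""
    _, is_tp, n_gt = match_detections(detections, gt, iou_threshold)
    tp = int(is_tp.sum())
    fp = int((~is_tp).sum())
    fn = n_gt - tp
    precision, recall = precision_recall(tp, fp, fn)
    return EvalReport(mae=spike_mae, precision=precision, recall=recall,
                      ap=_ap_from_matches(is_tp, n_gt))


def pr_curve_csv(
    detections: Sequence[Sequence[DetectionBox]],
    gt,
    path,
    iou_threshold: float = 0.25,
) -> None:
    """Write the cumulative precision-recall curve as CSV (score desc)."""
    scores, is_tp, n_gt = match_detections(detections, gt, iou_threshold)
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(~is_tp)
    with open(path, "w") as f:
        f.write("score,precision,recall\n")
        for s, tp, fp in zip(scores, tp_cum, fp_cum):
            f.write(f"{s},{tp / (tp + fp)},{tp / n_gt if n_gt else float('nan')}\n")


def motionmap_to_boxes(motion_map: np.ndarray, threshold: float) -> list[DetectionBox]:
    """Connected components of ``map >= threshold`` as scored boxes.

    Components use 4-connectivity; each box tightly bounds its component and
    is scored by the component's maximum map value.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    motion_map = np.asarray(motion_map, dtype=float)
    labeled, n = ndimage.label(motion_map >= threshold, structure=_CROSS)
    boxes = []
    for k, sl in enumerate(ndimage.find_objects(labeled), start=1):
        ys, xs = sl
        score = float(motion_map[sl][labeled[sl] == k].max())
        boxes.append(DetectionBox(x=xs.start, y=ys.start, w=xs.stop - xs.start,
                                  h=ys.stop - ys.start, score=min(score, 1.0)))
    return boxes
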