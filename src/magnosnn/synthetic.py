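"""Synthetic small-moving-target clips with ground truth and saliency labels.

Generates grayscale video clips that emulate the study conditions of the
drone-surveillance footage the model is meant for: 120 x 100 px frames at
20 fps, 5-10 s long, with one or more small (2-10 px) Gaussian-profile
targets moving along piecewise-linear paths over static, drifting-cloud,
urban-clutter, or exposure-ramp backgrounds.  Every clip comes with per-frame
target masks and tight bounding boxes, and :func:`build_dataset` additionally
writes motion-saliency labels produced by the magnocellular reference filter,
so the whole pipeline is testable without any external footage.

Backgrounds:

- ``uniform``: constant mid-gray;
- ``cloud_drift``: low-spatial-frequency value noise advected at <= 0.5
  px/frame;
- ``urban_clutter``: a static high-frequency pattern of rectangles;
- ``exposure``: a slow global gain ramp over a static scene.

Target photometric contrast is sampled in [0.2, 0.8] against the local
background, polarity chosen so the blob stays within [0, 1].
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from magnosnn.magno import RetinaFilterParams, photoreceptor_adapt, _opl_lowpass, \
    ganglion_lowpass_compress, _minmax_normalize

__all__ = [
    "ClipConfig",
    "VideoClip",
    "GroundTruth",
    "generate_clip",
    "magno_label_sequence",
    "build_dataset",
    "load_manifest",
]

Background = Literal["uniform", "cloud_drift", "urban_clutter", "exposure"]
BACKGROUNDS: tuple[str, ...] = ("uniform", "cloud_drift", "urban_clutter", "exposure")

#: FWHM of a Gaussian in units of sigma
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ClipConfig:
    """Parameters of one synthetic clip."""

    height: int = 100
    width: int = 120
    fps: int = 20
    duration_s: float = 5.0
    n_targets: int = 1
    target_size_px: tuple[int, int] = (2, 10)
    background: str = "uniform"
    target_speed_px_per_frame: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background not in BACKGROUNDS:
            raise ValueError(f"unknown background {self.background!r}; choose from {BACKGROUNDS}")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("fps and duration_s must be positive")
        if self.n_targets < 0:
            raise ValueError("n_targets must be >= 0")
        lo, hi = self.target_size_px
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid target size range {self.target_size_px}")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass
class VideoClip:
    frames: np.ndarray  # (T, H, W) float in [0, 1]
    fps: int
    duration_s: float


@dataclass
class GroundTruth:
    """Per-frame target masks and tight bounding boxes.

    ``masks`` is the union over targets; ``boxes`` has shape
    (T, n_targets, 4) with rows (x, y, w, h), 0-based, top-left origin,
    half-open.
    """

    masks: np.ndarray  # (T, H, W) bool
    boxes: np.ndarray  # (T, n_targets, 4) int


def _background_frames(config: ClipConfig, rng: np.random.Generator) -> np.ndarray:
    h, w, T = config.height, config.width, config.n_frames
    if config.background == "uniform":
        level = rng.uniform(0.3, 0.6)
        return np.full((T, h, w), level)
    if config.background == "cloud_drift":
        drift_speed = rng.uniform(0.2, 0.5)  # px/frame; clouds stay slower than targets
        angle = rng.uniform(0, 2 * np.pi)
        vy, vx = drift_speed * np.sin(angle), drift_speed * np.cos(angle)
        pad = int(np.ceil(drift_speed * T)) + 2
        big = gaussian_filter(rng.standard_normal((h + 2 * pad, w + 2 * pad)), sigma=8.0)
        big = 0.2 + 0.5 * _minmax_normalize(big)
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        frames = np.empty((T, h, w))
        for t in range(T):
            coords = np.array([yy + pad + vy * t, xx + pad + vx * t])
            frames[t] = map_coordinates(big, coords, order=1, mode="nearest")
        return frames
    if config.background == "urban_clutter":
        base = np.full((h, w), 0.35)
        for _ in range(40):
            rh = rng.integers(2, max(3, h // 6))
            rw = rng.integers(2, max(3, w // 6))
            y = rng.integers(0, h - rh)
            x = rng.integers(0, w - rw)
            base[y:y + rh, x:x + rw] = rng.uniform(0.1, 0.9)
        return np.repeat(base[None], T, axis=0)
    # exposure: static scene under a slow global gain ramp
    base = np.full((h, w), rng.uniform(0.4, 0.55))
    gain = np.linspace(0.85, 1.15, T)
    return np.clip(base[None] * gain[:, None, None], 0.0, 1.0)


def _target_track(config: ClipConfig, rng: np.random.Generator, margin: float) -> np.ndarray:
    """(T, 2) center positions (y, x); piecewise-linear, reflecting at margins."""
    h, w, T = config.height, config.width, config.n_frames
    if 2 * margin >= min(h, w) - 1:
        raise ValueError(
            f"target too large for frame: margin {margin:.1f} px in {h}x{w} frame")
    pos = np.array([rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin)])
    angle = rng.uniform(0, 2 * np.pi)
    vel = config.target_speed_px_per_frame * np.array([np.sin(angle), np.cos(angle)])
    turn_every = max(1, int(rng.integers(15, 40)))  # frames between direction changes
    track = np.empty((T, 2))
    for t in range(T):
        track[t] = pos
        if config.target_speed_px_per_frame > 0 and t % turn_every == turn_every - 1:
            angle = rng.uniform(0, 2 * np.pi)
            vel = config.target_speed_px_per_frame * np.array([np.sin(angle), np.cos(angle)])
        pos = pos + vel
        for axis, limit in ((0, h - 1), (1, w - 1)):  # reflect to stay inside
            if pos[axis] < margin:
                pos[axis] = 2 * margin - pos[axis]
                vel[axis] = -vel[axis]
            elif pos[axis] > limit - margin:
                pos[axis] = 2 * (limit - margin) - pos[axis]
                vel[axis] = -vel[axis]
    return track


def generate_clip(config: ClipConfig) -> tuple[VideoClip, GroundTruth]:
    """Render one clip with its ground truth; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    h, w, T = config.height, config.width, config.n_frames
    frames = _background_frames(config, rng)
    masks = np.zeros((T, h, w), dtype=bool)
    boxes = np.zeros((T, config.n_targets, 4), dtype=np.int64)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for k in range(config.n_targets):
        size = int(rng.integers(config.target_size_px[0], config.target_size_px[1] + 1))
        sigma = size / _FWHM
        radius = size / 2.0  # half-intensity radius: the mask extent
        contrast = rng.uniform(0.2, 0.8)
        track = _target_track(config, rng, margin=radius + 1.0)
        for t in range(T):
            cy, cx = track[t]
            profile = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2))
            local = frames[t, int(round(cy)), int(round(cx))]
            polarity = 1.0 if local < 0.5 else -1.0  # stay within [0, 1]
            frames[t] = np.clip(frames[t] + polarity * contrast * profile, 0.0, 1.0)
            mask = profile >= 0.5
            masks[t] |= mask
            ys, xs = np.nonzero(mask)
            boxes[t, k] = (xs.min(), ys.min(), xs.max() - xs.min() + 1, ys.max() - ys.min() + 1)
    clip = VideoClip(frames=np.clip(frames, 0.0, 1.0), fps=config.fps, duration_s=config.duration_s)
    return clip, GroundTruth(masks=masks, boxes=boxes)


def _box_mask(boxes: np.ndarray, shape: tuple[int, int], dilate: int = 0) -> np.ndarray:
    """Boolean mask covering all boxes of one frame, dilated by ``dilate`` px."""
    mask = np.zeros(shape, dtype=bool)
    for x, y, bw, bh in boxes:
        y0, y1 = max(0, y - dilate), min(shape[0], y + bh + dilate)
        x0, x1 = max(0, x - dilate), min(shape[1], x + bw + dilate)
        mask[y0:y1, x0:x1] = True
    return mask


def magno_label_sequence(
    frames: np.ndarray,
    params: RetinaFilterParams | None = None,
    box_masks: np.ndarray | None = None,
) -> np.ndarray:
    """Saliency labels for frames 1..T-1 of a clip (frame 0 has no history).

    Streams the magnocellular chain over the clip, maintaining the EMA
    background incrementally; label k corresponds to frame k+1 and is
    identical to ``magno_label(frames[:k+2])``.  ``box_masks`` (length T-1,
    aligned to the labels) restricts each label to its salient regions.
    """
    if params is None:
        params = RetinaFilterParams()
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    alpha = 1.0 / params.temporal_tau
    labels = np.empty((frames.shape[0] - 1,) + frames.shape[1:])
    background = None
    for t, frame in enumerate(frames):
        filtered = _opl_lowpass(photoreceptor_adapt(frame, params), params)
        if background is None:
            background = filtered
            continue
        saliency = ganglion_lowpass_compress(np.abs(filtered - background), params)
        if box_masks is not None:
            saliency = np.where(box_masks[t - 1], saliency, 0.0)
        labels[t - 1] = _minmax_normalize(saliency)
        background = (1.0 - alpha) * background + alpha * filtered
    return labels


def build_dataset(
    n_train: int,
    n_test: int,
    base_config: ClipConfig,
    out_dir: str | os.PathLike,
    filter_params: RetinaFilterParams | None = None,
) -> dict:
    """Generate and write a full dataset; returns (and writes) the manifest.

    Layout: ``clips/<id>/frames/%05d.png``, ``clips/<id>/labels/%05d.png``
    (frames 1..T-1; labels retain only content within the ground-truth boxes),
    ``clips/<id>/masks/%05d.png``, ``clips/<id>/gt.json``, plus top-level
    ``splits.json`` and ``manifest.json``.  Backgrounds cycle through the
    four scene classes; clip k uses seed ``base_config.seed + k``.
    """
    import imageio.v3 as iio

    root = Path(out_dir)
    try:
        (root / "clips").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {root}: {exc}") from exc
    entries, splits = [], {"train": [], "test": []}
    for k in range(n_train + n_test):
        split = "train" if k < n_train else "test"
        config = ClipConfig(**{**asdict(base_config),
                               "background": BACKGROUNDS[k % len(BACKGROUNDS)],
                               "seed": base_config.seed + k})
        clip_id = f"clip_{k:04d}"
        clip, gt = generate_clip(config)
        box_masks = np.stack([_box_mask(gt.boxes[t], clip.frames.shape[1:])
                              for t in range(1, config.n_frames)])
        labels = magno_label_sequence(clip.frames, filter_params, box_masks=box_masks)
        cdir = root / "clips" / clip_id
        for sub in ("frames", "labels", "masks"):
            (cdir / sub).mkdir(parents=True, exist_ok=True)
        for t in range(config.n_frames):
            iio.imwrite(cdir / "frames" / f"{t:05d}.png",
                        np.rint(clip.frames[t] * 255).astype(np.uint8))
            iio.imwrite(cdir / "masks" / f"{t:05d}.png",
                        (gt.masks[t] * 255).astype(np.uint8))
        for t in range(1, config.n_frames):
            iio.imwrite(cdir / "labels" / f"{t:05d}.png",
                        np.rint(labels[t - 1] * 255).astype(np.uint8))
        with open(cdir / "gt.json", "w") as f:
            json.dump({"clip_id": clip_id, "config": asdict(config),
                       "boxes": gt.boxes.tolist()}, f)
        entries.append({"id": clip_id, "split": split, "n_frames": config.n_frames,
                        "n_labels": config.n_frames - 1, "background": config.background,
                        "seed": config.seed, "path": str(Path("clips") / clip_id)})
        splits[split].append(clip_id)
    import hashlib

    params_used = asdict(filter_params or RetinaFilterParams())
    params_hash = hashlib.sha256(
        json.dumps(params_used, sort_keys=True).encode()).hexdigest()[:16]
    manifest = {"clips": entries, "height": base_config.height, "width": base_config.width,
                "fps": base_config.fps, "label_filter_params": params_used,
                "label_params_hash": params_hash}
    with open(root / "splits.json", "w") as f:
        json.dump(splits, f, indent=1)
    with open(root / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest


def load_manifest(root: str | os.PathLike) -> dict:
    root = Path(root)
    path = root / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json under {root}")
    with open(path) as f:
        return json.load(f)
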