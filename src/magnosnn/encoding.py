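"""Time-to-first-spike latency coding of video frames.

Each pixel of a normalized grayscale frame is represented by the time of a
single spike on the discrete axis ``{0, ..., t_max}``::

    T_i = round((1 - I_i) * t_max)

so maximal intensity fires at step 0 and zero intensity fires at the last
step.  A neuron that never crosses threshold downstream is assigned the same
terminal time ``t_max`` (a forced, minimal-information spike), which keeps a
spike train a dense length-N integer vector.  Decoding inverts the code:
``value = 1 - T / t_max``.

Pixel-to-neuron flattening is row-major from the top-left corner; this order
is fixed so that weight checkpoints are portable across machines.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SpikeTrain",
    "encode_frame",
    "decode_spiketrain",
    "load_frames",
    "save_motion_map",
    "plot_spike_raster",
]

#: file extensions accepted when reading a frame directory
_FRAME_EXTENSIONS = (".png", ".tif", ".tiff")
_VIDEO_EXTENSIONS = (".avi", ".mp4", ".mov", ".mkv")


@dataclass(frozen=True)
class SpikeTrain:
    """Single spike time per neuron on the integer axis ``{0, ..., t_max}``.

    ``times[i] == t_max`` marks a neuron that did not fire on its own and was
    forced to emit the terminal minimal-information spike.
    """

    times: np.ndarray
    t_max: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times)
        if not np.issubdtype(times.dtype, np.integer):
            raise TypeError(f"spike times must be integers, got dtype {times.dtype}")
        if self.t_max < 1:
            raise ValueError(f"t_max must be >= 1, got {self.t_max}")
        if times.size and (times.min() < 0 or times.max() > self.t_max):
            raise ValueError(
                f"spike times must lie in [0, {self.t_max}], "
                f"got range [{times.min()}, {times.max()}]"
            )
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.size

    @property
    def fired(self) -> np.ndarray:
        """Boolean mask of neurons that fired before the forced terminal spike."""
        return self.times < self.t_max


def _validate_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"frame must be 2-D (H, W), got shape {frame.shape}")
    if not np.isfinite(frame).all():
        raise ValueError("frame contains non-finite values")
    lo, hi = frame.min(), frame.max()
    if lo < 0.0 or hi > 1.0:
        raise ValueError(f"frame values must lie in [0, 1], got range [{lo}, {hi}]")
    return frame


def encode_frame(frame: np.ndarray, t_max: int) -> SpikeTrain:
    """Encode a normalized frame as one spike time per pixel.

    Parameters
    ----------
    frame
        2-D array of luminance values in ``[0, 1]``.
    t_max
        Maximum time step of the spike sequence (>= 1).

    Returns
    -------
    SpikeTrain
        ``times[i] = round((1 - I_i) * t_max)`` with pixels flattened
        row-major; higher intensity never fires later than lower intensity.
    """
    if t_max < 1:
        raise ValueError(f"t_max must be >= 1, got {t_max}")
    frame = _validate_frame(frame)
    times = np.rint((1.0 - frame.ravel(order="C")) * t_max).astype(np.int64)
    return SpikeTrain(times=times, t_max=int(t_max))


def decode_spiketrain(train: SpikeTrain, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Decode spike times back to intensities: ``value = 1 - T / t_max``.

    The earliest possible spike (t=0) maps to 1.0 and the forced terminal
    spike maps to 0.0.  If ``shape`` is given the flat vector is reshaped
    row-major into an H x W motion map.
    """
    values = 1.0 - train.times / train.t_max
    if shape is not None:
        values = values.reshape(shape)
    return values


def load_frames(path: str | os.PathLike) -> np.ndarray:
    """Read a clip as a (T, H, W) float array of values in [0, 1].

    ``path`` must be a directory of single-channel PNG/TIFF frames, read in
    lexicographic order.  8-bit images are divided by 255, 16-bit by 65535.
    Video containers are not supported; export the frames first.
    """
    import imageio.v3 as iio

    p = Path(path)
    if p.suffix.lower() in _VIDEO_EXTENSIONS:
        raise ValueError(
            f"video containers are not supported ({p.name}); "
            "export the clip to a directory of PNG/TIFF frames first"
        )
    if not p.is_dir():
        raise FileNotFoundError(f"frame directory not found: {p}")
    files = sorted(f for f in p.iterdir() if f.suffix.lower() in _FRAME_EXTENSIONS)
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF frames found in {p}")
    frames = []
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:  # collapse RGB(A) to luminance
            img = img[..., :3].mean(axis=-1)
        if img.dtype == np.uint8:
            img = img / 255.0
        elif img.dtype == np.uint16:
            img = img / 65535.0
        else:
            img = img.astype(float)
        frames.append(np.clip(img, 0.0, 1.0))
    stack = np.stack(frames)
    return stack


def save_motion_map(path: str | os.PathLike, motion_map: np.ndarray) -> None:
    """Write a [0, 1] motion map as an 8-bit single-channel PNG."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(motion_map, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.rint(arr * 255).astype(np.uint8))


def plot_spike_raster(train: SpikeTrain, path: str | os.PathLike | None = None):
    """Spike raster of a train: neuron index vs. spike time.

    Returns the matplotlib figure; saves a PNG when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(train.times, np.arange(len(train)), s=0.5, marker="|", linewidths=0.5)
    ax.set_xlabel("time step")
    ax.set_ylabel("neuron index")
    ax.set_xlim(-1, train.t_max + 1)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
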