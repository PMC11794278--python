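"""Magnocellular-pathway reference filter: the motion-saliency label generator.

The retinal magnocellular channel is modeled as a four-stage chain acting on
a short grayscale frame history:

1. photoreceptor adaptation — local luminance normalization
   ``I' = I / (I_local_mean + a)``, compressing dark regions more than bright
   ones so the response is roughly invariant to illumination level;
2. outer-plexiform spatial low-pass (Gaussian) followed by a temporal
   high-pass: an exponential-moving-average background with time constant
   ``tau`` frames, response ``|F_t - B_{t-1}|`` — ON and OFF channels are
   collapsed into the absolute temporal difference;
3. ganglion-cell spatial low-pass (Gaussian) with a compressive output
   nonlinearity ``x / (x + c)``;
4. per-frame min-max normalization to [0, 1] (a constant map normalizes to
   all zeros).

Static scenes yield an exactly zero label; a small target translating at
~1 px/frame yields a near-saturated response at its leading and trailing
edges.  The filter constants are configurable; the defaults were chosen so
that this regime holds for drone-sized (2-10 px) targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "RetinaFilterParams",
    "photoreceptor_adapt",
    "magno_temporal_highpass",
    "ganglion_lowpass_compress",
    "magno_label",
]

#: Gaussian sigma (px) of the luminance-adaptation pooling neighborhood
ADAPT_POOL_SIGMA = 5.0


@dataclass(frozen=True)
class RetinaFilterParams:
    """Constants of the magnocellular filter chain.

    photoreceptor_adapt_strength : half-saturation constant ``a`` of the
        luminance normalization (unitless).
    opl_spatial_sigma : Gaussian sigma (px) of the outer-plexiform low-pass;
        0 disables it.
    temporal_tau : EMA background time constant (frames, >= 1).
    ganglion_spatial_sigma : Gaussian sigma (px) of the ganglion low-pass.
    compression_gain : half-saturation constant ``c`` of the output
        compression ``x / (x + c)``.
    """

    photoreceptor_adapt_strength: float = 0.1
    opl_spatial_sigma: float = 1.0
    temporal_tau: float = 2.0
    ganglion_spatial_sigma: float = 2.0
    compression_gain: float = 0.1

    def __post_init__(self) -> None:
        for name in ("photoreceptor_adapt_strength", "opl_spatial_sigma",
                     "ganglion_spatial_sigma", "compression_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.temporal_tau < 1:
            raise ValueError(f"temporal_tau must be >= 1 frame, got {self.temporal_tau}")


def photoreceptor_adapt(frame: np.ndarray, params: RetinaFilterParams) -> np.ndarray:
    """Local luminance normalization with a compressive response.

    ``I' = I / (I_pool + a)`` where ``I_pool`` is a Gaussian local mean;
    the result is rescaled into [0, 1] only when it exceeds 1, so a uniform
    frame stays uniform.
    """
    frame = np.asarray(frame, dtype=float)
    local_mean = gaussian_filter(frame, sigma=ADAPT_POOL_SIGMA, mode="nearest")
    adapted = frame / (local_mean + params.photoreceptor_adapt_strength)
    peak = adapted.max()
    if peak > 1.0:
        adapted = adapted / peak
    return adapted


def _opl_lowpass(frame: np.ndarray, params: RetinaFilterParams) -> np.ndarray:
    if params.opl_spatial_sigma <= 0:
        return frame
    return gaussian_filter(frame, sigma=params.opl_spatial_sigma, mode="nearest")


def magno_temporal_highpass(history: Sequence[np.ndarray], params: RetinaFilterParams) -> np.ndarray:
    """Temporal high-pass of the newest frame against an EMA background.

    Frames (newest last) are spatially low-passed, then a background is
    tracked as ``B_t = (1 - 1/tau) B_{t-1} + (1/tau) F_t`` starting from
    ``B_0 = F_0``.  The response is ``|F_T - B_{T-1}|``: the newest frame
    against the background accumulated before it arrived.
    """
    if len(history) < 2:
        raise ValueError(f"need at least 2 frames of history, got {len(history)}")
    alpha = 1.0 / params.temporal_tau
    filtered = [_opl_lowpass(np.asarray(f, dtype=float), params) for f in history]
    background = filtered[0]
    for frame in filtered[1:-1]:
        background = (1.0 - alpha) * background + alpha * frame
    return np.abs(filtered[-1] - background)


def ganglion_lowpass_compress(response: np.ndarray, params: RetinaFilterParams) -> np.ndarray:
    """Ganglion stage: Gaussian smoothing then compression ``x / (x + c)``."""
    response = np.asarray(response, dtype=float)
    if params.ganglion_spatial_sigma > 0:
        response = gaussian_filter(response, sigma=params.ganglion_spatial_sigma, mode="nearest")
    return response / (response + params.compression_gain)


def _minmax_normalize(saliency: np.ndarray) -> np.ndarray:
    lo, hi = saliency.min(), saliency.max()
    if hi - lo <= 0:
        return np.zeros_like(saliency)
    return (saliency - lo) / (hi - lo)


def magno_label(
    history: Sequence[np.ndarray],
    params: RetinaFilterParams | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Motion-saliency label for the newest frame of a history.

    Runs the full chain (adaptation -> temporal high-pass -> ganglion
    low-pass + compression) and min-max normalizes to [0, 1].  When ``mask``
    is given (boolean, H x W) the saliency outside it is zeroed before
    normalization — used when building training labels so that only content
    within annotated salient regions is retained.
    """
    if params is None:
        params = RetinaFilterParams()
    if len(history) < 2:
        raise ValueError(f"need at least 2 frames of history, got {len(history)}")
    adapted = [photoreceptor_adapt(f, params) for f in history]
    response = magno_temporal_highpass(adapted, params)
    saliency = ganglion_lowpass_compress(response, params)
    if mask is not None:
        saliency = np.where(np.asarray(mask, dtype=bool), saliency, 0.0)
    return _minmax_normalize(saliency)
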