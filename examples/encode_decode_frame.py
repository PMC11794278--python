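"""Latency-code a frame and decode it back.

Builds a synthetic luminance ramp, encodes every pixel as a single spike time
(bright pixels fire early, dark pixels late, step 256 is the forced terminal
spike), and decodes the train back to an intensity map.  The printed maximum
round-trip error is bounded by half a time step, 1/(2*256) ~ 0.002.
"""

import numpy as np

from magnosnn import encode_frame, decode_spiketrain

frame = np.linspace(0, 1, 12 * 16).reshape(12, 16)
t_max = 256

train = encode_frame(frame, t_max)
print(f"frame {frame.shape}, t_max={t_max}")
print(f"spike times: min={train.times.min()} (brightest pixel) "
      f"max={train.times.max()} (darkest pixel)")
print(f"neurons with a forced terminal spike: {(~train.fired).sum()}")

decoded = decode_spiketrain(train, shape=frame.shape)
err = np.max(np.abs(decoded - frame))
print(f"max round-trip error: {err:.5f} (bound {1 / (2 * t_max):.5f})")
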