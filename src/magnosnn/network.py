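"""Two-layer fully connected spiking network over discrete time.

Architecture: input layer (one neuron per pixel, latency-coded) -> dense
weights -> hidden IF layer -> dense weights -> output IF layer.  Both weight
matrices are initialized i.i.d. uniform on [w_min, w_max] = [-1, 1].  Frames
are processed independently: membranes are reset after every frame, so the
forward pass is stateless across frames and all temporal context enters
through the supervision labels, which summarize a short frame history.

``run_layer`` uses a cumulative-potential formulation: with no leak and at
most one spike per window, a neuron's potential at step t (ignoring its own
reset) is the running sum of weighted presynaptic spikes delivered up to t,
and its fire time is the first step where that sum meets the dynamic
threshold with strictly positive net drive.  This is exactly equivalent to
stepping :func:`magnosnn.neurons.if_step` over t = 0..t_max (see
``run_layer_stepwise`` and the oracle-equivalence tests) but runs as a few
dense array operations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from magnosnn.encoding import SpikeTrain, encode_frame
from magnosnn.neurons import MembraneState, NeuronParams, if_step

__all__ = [
    "NetworkConfig",
    "init_network",
    "run_layer",
    "run_layer_stepwise",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Geometry and neuron parameters of the network.

    ``hidden_size`` defaults to ``height * width`` so that input, hidden and
    output layers share one size (the reference configuration at 120 x 100 is
    12,000 neurons per layer); tests and scaled experiments use smaller
    geometries.
    """

    height: int = 100
    width: int = 120
    hidden_size: int | None = None
    t_max: int = 256
    neuron: NeuronParams = field(default_factory=NeuronParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError(f"frame geometry must be positive, got {self.height}x{self.width}")
        if self.hidden_size is None:
            object.__setattr__(self, "hidden_size", self.height * self.width)
        if self.hidden_size <= 0:
            raise ValueError(f"hidden_size must be positive, got {self.hidden_size}")
        if self.neuron.t_max != self.t_max:
            object.__setattr__(self, "neuron", NeuronParams(
                v_th=self.neuron.v_th, v_reset=self.neuron.v_reset,
                theta=self.neuron.theta, t_max=self.t_max))

    @property
    def n_input(self) -> int:
        return self.height * self.width

    @property
    def n_output(self) -> int:
        return self.height * self.width


#: weight initialization bounds
W_MIN, W_MAX = -1.0, 1.0


def init_network(config: NetworkConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw both weight matrices i.i.d. uniform on [-1, 1] from the seed."""
    rng = np.random.default_rng(config.seed)
    w1 = rng.uniform(W_MIN, W_MAX, size=(config.n_input, config.hidden_size))
    w2 = rng.uniform(W_MIN, W_MAX, size=(config.hidden_size, config.n_output))
    return w1, w2


def _delivered_current(weights: np.ndarray, in_spikes: SpikeTrain) -> np.ndarray:
    """(t_max+1, N_post) array: summed synaptic input arriving at each step.

    Computed as a sparse one-hot (time x pre) matrix times the weight matrix,
    which is much faster than scattered accumulation for dense layers.
    """
    from scipy.sparse import csr_matrix

    n_pre, n_post = weights.shape
    onehot = csr_matrix(
        (np.ones(n_pre), (in_spikes.times, np.arange(n_pre))),
        shape=(in_spikes.t_max + 1, n_pre),
    )
    return onehot @ weights


def run_layer(weights: np.ndarray, in_spikes: SpikeTrain, params: NeuronParams) -> SpikeTrain:
    """Simulate one IF layer over t = 0..t_max; vectorized.

    Presynaptic neuron i delivers its weight row at its spike time.  A
    postsynaptic neuron fires at the first step where its accumulated
    potential meets ``v_th + theta * t`` and strictly exceeds ``v_reset``;
    neurons that never cross are assigned the forced terminal spike t_max.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != len(in_spikes):
        raise ValueError(
            f"weights shape {weights.shape} incompatible with {len(in_spikes)} presynaptic neurons")
    if in_spikes.t_max != params.t_max:
        raise ValueError(f"spike train t_max {in_spikes.t_max} != neuron t_max {params.t_max}")
    potential = np.cumsum(_delivered_current(weights, in_spikes), axis=0)
    steps = np.arange(params.t_max + 1, dtype=float)
    thresholds = params.v_th + params.theta * steps
    crossing = (potential >= thresholds[:, None]) & (potential > params.v_reset)
    first = np.argmax(crossing, axis=0)
    any_cross = crossing.any(axis=0)
    times = np.where(any_cross, first, params.t_max).astype(np.int64)
    return SpikeTrain(times=times, t_max=params.t_max)


def run_layer_stepwise(weights: np.ndarray, in_spikes: SpikeTrain, params: NeuronParams) -> SpikeTrain:
    """Reference layer simulation that steps :func:`if_step` explicitly."""
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != len(in_spikes):
        raise ValueError(
            f"weights shape {weights.shape} incompatible with {len(in_spikes)} presynaptic neurons")
    delivered = _delivered_current(weights, in_spikes)
    state = MembraneState.zeros(weights.shape[1], params)
    for t in range(params.t_max + 1):
        state = if_step(state, delivered[t], t, params)
    times = np.where(state.fired, state.fire_time, params.t_max).astype(np.int64)
    return SpikeTrain(times=times, t_max=params.t_max)


def forward(
    frames: np.ndarray,
    weights: tuple[np.ndarray, np.ndarray],
    config: NetworkConfig,
) -> list[tuple[SpikeTrain, SpikeTrain]]:
    """Run the full network frame by frame.

    Membranes are reset between frames (each frame starts from a fresh
    state), so identical frames produce identical outputs.  Returns one
    (hidden, output) spike-train pair per frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 0:
        raise ValueError("frames must be nonempty")
    if frames.shape[1:] != (config.height, config.width):
        raise ValueError(
            f"frame geometry {frames.shape[1:]} != config {config.height}x{config.width}")
    w1, w2 = weights
    results = []
    for frame in frames:
        in_spikes = encode_frame(frame, config.t_max)
        hidden = run_layer(w1, in_spikes, config.neuron)
        output = run_layer(w2, hidden, config.neuron)
        results.append((hidden, output))
    return results


def save_checkpoint(path: str | os.PathLike, weights: tuple[np.ndarray, np.ndarray], config: NetworkConfig) -> None:
    """Write both weight matrices plus configuration metadata to HDF5."""
    import h5py

    w1, w2 = weights
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("w1", data=w1)
        f.create_dataset("w2", data=w2)
        f.attrs["height"] = config.height
        f.attrs["width"] = config.width
        f.attrs["hidden_size"] = config.hidden_size
        f.attrs["t_max"] = config.t_max
        f.attrs["theta"] = config.neuron.theta
        f.attrs["v_th"] = config.neuron.v_th
        f.attrs["v_reset"] = config.neuron.v_reset
        f.attrs["seed"] = config.seed


def load_checkpoint(path: str | os.PathLike) -> tuple[tuple[np.ndarray, np.ndarray], NetworkConfig]:
    """Read a checkpoint written by :func:`save_checkpoint`."""
    import h5py

    with h5py.File(Path(path), "r") as f:
        w1 = f["w1"][...]
        w2 = f["w2"][...]
        config = NetworkConfig(
            height=int(f.attrs["height"]),
            width=int(f.attrs["width"]),
            hidden_size=int(f.attrs["hidden_size"]),
            t_max=int(f.attrs["t_max"]),
            neuron=NeuronParams(
                v_th=float(f.attrs["v_th"]),
                v_reset=float(f.attrs["v_reset"]),
                theta=float(f.attrs["theta"]),
                t_max=int(f.attrs["t_max"]),
            ),
            seed=int(f.attrs["seed"]),
        )
    return (w1, w2), config
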