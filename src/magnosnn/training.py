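"""Spike-time supervised learning with dynamic thresholds and an STDP gate.

The loss is a mean squared spike-time error between the output train and the
latency-encoded saliency label,

    L = 1/2 * sum_j mu * (T_out_j - T_label_j)^2 / t_max^2,

minimized by SGD through a surrogate: the IF membrane approximates a ReLU
activation and the activation relates to the firing time as
``y ~ t_max - t``, giving the output error term

    delta_j = -mu * (T_out_j - T_label_j) / t_max^2.

Each weight update is gated by an STDP sign factor ``eps_j`` computed from
the order of label vs. output spike (+1 label later, -1 label earlier, 0 when
either is the forced terminal spike) and by the presence of an early
presynaptic spike ``S_i``:

    w_ji <- w_ji + beta * delta_j * S_i * eps_j.

Three update modes are provided, because the rule as printed does not descend
its own loss (see docs/methods.md for the full analysis):

- ``"literal"``: ``beta * delta_j * S_i * eps_j`` exactly as written.  Since
  ``sign(eps_j) == sign(delta_j)`` whenever ``eps_j`` is nonzero, every active
  update is nonnegative (pure potentiation), and the zero branch of the gate
  freezes every synapse whose label or output spike sits at t_max.
- ``"magnitude"``: ``beta * |delta_j| * S_i * eps_j``, letting the STDP factor
  alone set the direction (algebraically equal to ``beta * delta_j * S_i``
  under the gate).
- ``"descent"`` (default): ``-beta * delta_j * S_i`` for both layers with no
  gate — the exact SGD direction under the stated surrogate (``dt/dV = -1``,
  ReLU derivative), treating the forced terminal spike as a valid spike time
  so that silent neurons can be recruited and spurious early spikes can be
  suppressed.  This is the only variant whose fixed point is
  ``t_out = t_label``.

Hidden-layer error terms are backpropagated through the output weights with a
ReLU-derivative surrogate (1 where the hidden neuron fired before t_max, else
0); in the gated modes the output eps gate is folded into the backpropagated
sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from magnosnn.encoding import SpikeTrain, encode_frame
from magnosnn.network import NetworkConfig, init_network, run_layer

__all__ = [
    "TrainParams",
    "TrainRecord",
    "stdp_factor",
    "stdp_factors",
    "spike_time_loss",
    "output_delta",
    "hidden_delta",
    "update_weights",
    "train",
    "evaluate_mae",
    "search_theta",
]

#: first usable window index: the network consumes 3-frame windows, so the
#: earliest supervised frame is index 2 (its label still needs frame >= 1)
WINDOW = 3


@dataclass(frozen=True)
class TrainParams:
    """Learning hyperparameters.

    mu : time-error update parameter of the loss (default 0.02).
    beta : SGD learning rate (default 1e-6).
    epochs : number of passes over the training clips (default 20).
    stdp_mode : "descent" (default) follows the surrogate gradient;
        "literal" applies ``beta * delta * S * eps`` as printed;
        "magnitude" applies ``beta * |delta| * S * eps``.  See the module
        docstring.
    """

    mu: float = 0.02
    beta: float = 1e-6
    epochs: int = 20
    seed: int = 0
    stdp_mode: str = "descent"

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.beta < 0:
            raise ValueError("mu must be > 0 and beta >= 0")
        if self.stdp_mode not in ("descent", "literal", "magnitude"):
            raise ValueError(
                f"stdp_mode must be 'descent', 'literal' or 'magnitude', got {self.stdp_mode!r}")


@dataclass(frozen=True)
class TrainRecord:
    epoch: int
    train_mae: float
    test_mae: float


def stdp_factor(t_label: int, t_out: int, t_max: int) -> int:
    """STDP sign factor for one output neuron.

    +1 when the label spikes later than the output, -1 when earlier, 0 when
    the times agree or either is the forced terminal spike at t_max.
    """
    if not (0 <= t_label <= t_max and 0 <= t_out <= t_max):
        raise ValueError("spike times must lie in [0, t_max]")
    if t_label == t_max or t_out == t_max or t_label == t_out:
        return 0
    return 1 if t_label > t_out else -1


def stdp_factors(t_label: np.ndarray, t_out: np.ndarray, t_max: int) -> np.ndarray:
    """Vectorized :func:`stdp_factor`."""
    t_label = np.asarray(t_label)
    t_out = np.asarray(t_out)
    eps = np.sign(t_label - t_out).astype(np.int64)
    eps[(t_label == t_max) | (t_out == t_max)] = 0
    return eps


def spike_time_loss(t_out: np.ndarray, t_label: np.ndarray, params: TrainParams, t_max: int) -> float:
    """Mean squared spike-time error ``1/2 sum mu (t_out - t_label)^2 / t_max^2``."""
    t_out = np.asarray(t_out, dtype=float)
    t_label = np.asarray(t_label, dtype=float)
    if t_out.shape != t_label.shape:
        raise ValueError(f"shape mismatch: {t_out.shape} vs {t_label.shape}")
    return 0.5 * params.mu * float(np.sum((t_out - t_label) ** 2)) / t_max ** 2


def output_delta(t_out: np.ndarray, t_label: np.ndarray, params: TrainParams, t_max: int) -> np.ndarray:
    """Output error term ``-mu (t_out - t_label) / t_max^2`` (elementwise)."""
    return -params.mu * (np.asarray(t_out, dtype=float) - np.asarray(t_label, dtype=float)) / t_max ** 2


def hidden_delta(deltas_out: np.ndarray, weights2: np.ndarray, hidden_spikes: SpikeTrain) -> np.ndarray:
    """Backpropagated hidden error with the ReLU-derivative surrogate.

    ``delta_i = (sum_j w2[i, j] * delta_out_j) * g_i`` where ``g_i`` is 1 for
    hidden neurons that fired before t_max and 0 for forced terminal spikes.
    """
    deltas_out = np.asarray(deltas_out, dtype=float)
    weights2 = np.asarray(weights2, dtype=float)
    if weights2.shape[1] != deltas_out.shape[0] or weights2.shape[0] != len(hidden_spikes):
        raise ValueError(
            f"dimension mismatch: w2 {weights2.shape}, deltas {deltas_out.shape}, "
            f"hidden {len(hidden_spikes)}")
    return (weights2 @ deltas_out) * hidden_spikes.fired


def update_weights(
    weights: np.ndarray,
    deltas: np.ndarray,
    pre_spikes: SpikeTrain,
    stdp: np.ndarray,
    params: TrainParams,
) -> np.ndarray:
    """Apply ``w_ji += beta * delta_j * S_i * eps_j`` in place and return w.

    ``S_i`` is 1 where presynaptic neuron i fired before t_max, 0 for the
    forced terminal spike (which carries minimal information).
    """
    deltas = np.asarray(deltas, dtype=float)
    stdp = np.asarray(stdp, dtype=float)
    if weights.shape != (len(pre_spikes), deltas.shape[0]) or stdp.shape != deltas.shape:
        raise ValueError(
            f"dimension mismatch: w {weights.shape}, pre {len(pre_spikes)}, "
            f"deltas {deltas.shape}, stdp {stdp.shape}")
    if params.stdp_mode == "magnitude":
        effective = np.abs(deltas) * stdp
    else:
        effective = deltas * stdp
    if not np.isfinite(effective).all():
        raise ValueError("non-finite weight update")
    cols = np.flatnonzero(effective)  # most error terms are zero: update sparsely
    if cols.size:
        rows = np.flatnonzero(pre_spikes.fired)
        weights[np.ix_(rows, cols)] += params.beta * effective[cols]
    return weights


def _iter_windows(clip: tuple[np.ndarray, np.ndarray]):
    """Yield (frame, label) for every 3-frame window of a clip.

    With membranes reset between frames, the first two frames of a window
    have no effect on its output, so only the last frame is forwarded; the
    multi-frame history enters through the label, which summarizes motion
    over the preceding frames.  ``labels[k]`` belongs to ``frames[k + 1]``.
    """
    frames, labels = clip
    if len(frames) != len(labels) + 1:
        raise ValueError(
            f"expected one label per frame after the first: {len(frames)} frames, "
            f"{len(labels)} labels")
    for t in range(WINDOW - 1, len(frames)):
        yield frames[t], labels[t - 1]


def _window_mae(out: SpikeTrain, t_label: np.ndarray) -> float:
    return float(np.mean(np.abs(out.times - t_label)))


def evaluate_mae(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    weights: tuple[np.ndarray, np.ndarray],
    config: NetworkConfig,
) -> float:
    """Mean spike-time MAE over all windows of a dataset (forward only)."""
    w1, w2 = weights
    total, count = 0.0, 0
    for clip in dataset:
        for frame, label in _iter_windows(clip):
            in_spikes = encode_frame(frame, config.t_max)
            hidden = run_layer(w1, in_spikes, config.neuron)
            out = run_layer(w2, hidden, config.neuron)
            total += _window_mae(out, encode_frame(label, config.t_max).times)
            count += 1
    if count == 0:
        raise ValueError("dataset has no usable windows")
    return total / count


def train(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    config: NetworkConfig,
    params: TrainParams,
    test_dataset: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    weights: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray], list[TrainRecord]]:
    """SGD over all 3-frame windows of the training clips.

    ``dataset`` items are ``(frames, labels)`` pairs: frames shaped
    (T, H, W) in [0, 1] and labels shaped (T-1, H, W) aligned to frames[1:].
    Per window: forward; encode the label; compute the STDP gate and the
    output/hidden error terms; update both weight matrices; membranes reset
    implicitly with the next frame.  Returns the trained weights and one
    record per epoch with the training MAE (measured on the outputs seen
    during the pass) and the held-out MAE (nan when no test set is given).
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    w1, w2 = init_network(config) if weights is None else weights
    rng = np.random.default_rng(params.seed)
    windows = [w for clip in dataset for w in _iter_windows(clip)]
    label_times = [encode_frame(label, config.t_max).times for _, label in windows]
    records: list[TrainRecord] = []
    for epoch in range(1, params.epochs + 1):
        order = rng.permutation(len(windows))
        total_mae = 0.0
        for idx in order:
            frame, _ = windows[idx]
            t_label = label_times[idx]
            in_spikes = encode_frame(frame, config.t_max)
            hidden = run_layer(w1, in_spikes, config.neuron)
            out = run_layer(w2, hidden, config.neuron)
            total_mae += _window_mae(out, t_label)
            d_out = output_delta(out.times, t_label, params, config.t_max)
            if params.stdp_mode == "descent":
                # exact surrogate-SGD direction: -beta * delta * S on both layers
                minus_one = np.full_like(d_out, -1.0)
                d_hidden = hidden_delta(d_out, w2, hidden)
                update_weights(w2, d_out, hidden, minus_one, params)
                update_weights(w1, d_hidden, in_spikes, np.full_like(d_hidden, -1.0), params)
            else:
                eps = stdp_factors(t_label, out.times, config.t_max)
                # fold the output STDP gate into the backpropagated hidden error
                d_hidden = hidden_delta(d_out * eps, w2, hidden)
                update_weights(w2, d_out, hidden, eps, params)
                update_weights(w1, d_hidden, in_spikes, np.ones_like(d_hidden), params)
        test_mae = (evaluate_mae(test_dataset, (w1, w2), config)
                    if test_dataset else float("nan"))
        records.append(TrainRecord(epoch=epoch, train_mae=total_mae / len(windows),
                                   test_mae=test_mae))
    return (w1, w2), records


def search_theta(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    config: NetworkConfig,
    thetas: Sequence[float],
) -> tuple[float, dict[float, float]]:
    """Grid search the dynamic-threshold slope against the label MAE.

    Evaluates the freshly initialized network's forward MAE for each
    candidate slope and returns the best one with the full profile.  The
    reference slope 0.5 stays the default; this helper exists because the
    optimal slope depends on the input statistics.
    """
    from dataclasses import replace
    from magnosnn.neurons import NeuronParams

    scores: dict[float, float] = {}
    for theta in thetas:
        cfg = replace(config, neuron=NeuronParams(
            v_th=config.neuron.v_th, v_reset=config.neuron.v_reset,
            theta=float(theta), t_max=config.t_max))
        scores[float(theta)] = evaluate_mae(dataset, init_network(cfg), cfg)
    best = min(scores, key=scores.get)
    return best, scores
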