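"""Integrate-and-fire dynamics with a time-linear dynamic threshold.

The membrane integrates weighted presynaptic spikes with no leak.  The firing
threshold grows linearly with the simulation step,

    D_th(t) = V_th + theta * t,

privileging early spikes, which under latency coding carry the most
information.  Each neuron fires at most once per frame window; firing resets
the potential to ``v_reset`` and freezes it there until the per-frame reset.

A neuron fires at step t only when its accumulated potential both meets the
dynamic threshold and strictly exceeds the resting potential.  The second
condition prevents the whole layer from firing vacuously at t = 0 where, with
the default V_th = 0, the threshold is zero: net-positive drive is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NeuronParams", "MembraneState", "dynamic_threshold", "if_step", "reset_membranes"]


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of the dynamic-threshold IF neuron.

    v_th : baseline threshold (mV), default 0.
    v_reset : resting potential (mV), default 0.
    theta : dynamic-threshold learning rate (threshold increase per time
        step), default 0.5.
    t_max : last step of the frame window; neurons that never cross emit the
        forced terminal spike there.
    """

    v_th: float = 0.0
    v_reset: float = 0.0
    theta: float = 0.5
    t_max: int = 256

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")
        if self.t_max < 1:
            raise ValueError(f"t_max must be >= 1, got {self.t_max}")
        if self.v_reset > self.v_th:
            raise ValueError("v_reset must not exceed the baseline threshold v_th")


@dataclass
class MembraneState:
    """Mutable per-neuron state over one frame window."""

    potential: np.ndarray
    fired: np.ndarray
    fire_time: np.ndarray

    @classmethod
    def zeros(cls, n: int, params: NeuronParams) -> "MembraneState":
        return cls(
            potential=np.full(n, params.v_reset, dtype=float),
            fired=np.zeros(n, dtype=bool),
            fire_time=np.zeros(n, dtype=np.int64),
        )


def dynamic_threshold(t: int, params: NeuronParams) -> float:
    """Firing threshold at step t: ``V_th + theta * t``."""
    if t < 0 or t > params.t_max:
        raise ValueError(f"time step {t} outside [0, {params.t_max}]")
    return params.v_th + params.theta * t


def if_step(state: MembraneState, input_current: np.ndarray, t: int, params: NeuronParams) -> MembraneState:
    """Advance one simulation step: integrate input, then test the threshold.

    ``input_current[i]`` is the summed synaptic weight of presynaptic neurons
    spiking at step t into neuron i.  Neurons that already fired in this
    window stay at ``v_reset`` and ignore further input.  The threshold test
    happens after integration at the same step.
    """
    current = np.asarray(input_current, dtype=float)
    if current.shape != state.potential.shape:
        raise ValueError(f"current shape {current.shape} != state shape {state.potential.shape}")
    if not np.isfinite(current).all():
        raise ValueError("non-finite input current")
    active = ~state.fired
    state.potential[active] += current[active]
    threshold = dynamic_threshold(t, params)
    crossing = active & (state.potential >= threshold) & (state.potential > params.v_reset)
    state.fire_time[crossing] = t
    state.fired[crossing] = True
    state.potential[crossing] = params.v_reset
    return state


def reset_membranes(state: MembraneState, params: NeuronParams) -> MembraneState:
    """Reset after a frame's forward (and backward) pass; idempotent."""
    state.potential[:] = params.v_reset
    state.fired[:] = False
    state.fire_time[:] = 0
    return state
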