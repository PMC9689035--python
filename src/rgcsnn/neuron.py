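"""Retinal-ganglion-cell (RGC) and leaky integrate-and-fire neuron dynamics.

The RGC unit is a Hodgkin–Huxley-flavoured spiking neuron: its membrane
potential integrates synaptic input minus an ion-channel current

    I_ion = g_Na * m^3 * h * (U - E_Na) + g_K * n^4 * (U - E_K) + g_L * (U - E_L)

and emits a spike whenever U strictly exceeds the firing threshold, after
which the threshold value is subtracted from the membrane (soft reset).
The iterative form advanced one simulation step at a time is

    U_t = U_{t-1} + (dt/C) * (I_syn - I_ion) - spike_{t-1} * V_th

All quantities live on a normalised, dimensionless scale compatible with
a threshold of 0.5 and convolution-scale input currents; the defaults
(g_Na = g_K = 0, small leak g_L) make the unit a leaky integrator while
keeping the full ion-channel form available through the parameters.

Training uses a rectangular surrogate in place of the spike derivative:
h1(U) = (1/a1) * 1[|U - V_th| < a1/2], which integrates to 1 for any a1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import autograd as ag

__all__ = [
    "NeuronParams", "MembraneState", "SpikeTrain",
    "ion_channel_current", "update_gating", "fire_and_reset",
    "rgc_step", "lif_step", "surrogate_grad", "SpikingLayer",
]


@dataclass
class NeuronParams:
    """Parameters of a spiking unit (RGC or LIF baseline).

    All values are dimensionless; ``dt`` is one simulation step.  The
    gating variables relax toward sigmoidal steady states at rate
    ``gating_rate`` per unit time (0 freezes them at their initial
    values m = h = 1, n = 0.5, the static-channel default).
    """

    v_th: float = 0.5
    a1: float = 1.0
    g_na: float = 0.0
    g_k: float = 0.0
    g_l: float = 0.1
    e_na: float = 1.0
    e_k: float = -1.0
    e_l: float = 0.0
    capacitance: float = 1.0
    dt: float = 1.0
    mode: str = "rgc"
    lif_decay: float = 0.5
    gating_rate: float = 0.0
    # sigmoid steady-state midpoints / slopes for m, n (activation) and h
    # (inactivation); only used when gating_rate > 0
    gate_mid: float = 0.25
    gate_slope: float = 0.1

    def __post_init__(self):
        if self.v_th <= 0:
            raise ValueError("v_th must be positive")
        if self.a1 <= 0:
            raise ValueError("a1 must be positive")
        if not 0 < self.lif_decay <= 1:
            raise ValueError("lif_decay must lie in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        if self.mode not in ("rgc", "lif"):
            raise ValueError(f"unknown neuron mode {self.mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        return cls(**d)


@dataclass
class MembraneState:
    """Per-unit membrane potential, gating variables and last spike flag."""

    u: np.ndarray
    m: np.ndarray
    n: np.ndarray
    h: np.ndarray
    last_spike: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "MembraneState":
        return cls(
            u=np.zeros(shape),
            m=np.ones(shape),
            n=np.full(shape, 0.5),
            h=np.ones(shape),
            last_spike=np.zeros(shape),
        )


@dataclass
class SpikeTrain:
    """Binary activations indexed [time step, channel(s), ...]."""

    values: np.ndarray
    t_steps: int = 8

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape[0] != self.t_steps:
            raise ValueError(
                f"leading dimension {self.values.shape[0]} != t_steps {self.t_steps}")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("spike train must be binary")

    @property
    def rate(self) -> np.ndarray:
        """Mean firing rate per unit over the simulation window."""
        return self.values.mean(axis=0)


def _check_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in neuron state")


def ion_channel_current(state: MembraneState, params: NeuronParams) -> np.ndarray:
    """Sodium + potassium + leak current through the membrane."""
    _check_finite(state.u, state.m, state.n, state.h)
    return (
        params.g_na * state.m ** 3 * state.h * (state.u - params.e_na)
        + params.g_k * state.n ** 4 * (state.u - params.e_k)
        + params.g_l * (state.u - params.e_l)
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def update_gating(state: MembraneState, params: NeuronParams) -> MembraneState:
    """One forward-Euler relaxation step of the gating variables.

    m and n relax toward an increasing sigmoid of U, h (inactivation)
    toward the mirrored sigmoid; results are clamped to [0, 1].
    """
    r = params.gating_rate * params.dt
    if r == 0.0:
        return state
    act = _sigmoid((state.u - params.gate_mid) / params.gate_slope)
    inact = 1.0 - act
    m = np.clip(state.m + r * (act - state.m), 0.0, 1.0)
    n = np.clip(state.n + r * (act - state.n), 0.0, 1.0)
    h = np.clip(state.h + r * (inact - state.h), 0.0, 1.0)
    return MembraneState(u=state.u, m=m, n=n, h=h, last_spike=state.last_spike)


def fire_and_reset(u: np.ndarray, params: NeuronParams):
    """Threshold crossing with soft reset.

    Where U strictly exceeds V_th the unit spikes and V_th is subtracted
    from the membrane; elsewhere the membrane is unchanged.  Returns
    ``(spikes, u_after)``.
    """
    _check_finite(u)
    spikes = (u > params.v_th).astype(np.float64)
    return spikes, u - spikes * params.v_th


def rgc_step(state: MembraneState, synaptic_input: np.ndarray,
             params: NeuronParams):
    """Advance an RGC population one simulation step.

    The stored membrane is the pre-reset potential; the previous step's
    spike flag carries the soft reset (−spike·V_th) into this update.
    Returns ``(new_state, spikes)``.
    """
    synaptic_input = np.asarray(synaptic_input, dtype=np.float64)
    if synaptic_input.shape != state.u.shape:
        raise ValueError(
            f"input shape {synaptic_input.shape} != state shape {state.u.shape}")
    i_ion = ion_channel_current(state, params)
    u_new = (state.u
             + (params.dt / params.capacitance) * (synaptic_input - i_ion)
             - state.last_spike * params.v_th)
    new_state = MembraneState(u=u_new, m=state.m, n=state.n, h=state.h,
                              last_spike=state.last_spike)
    new_state = update_gating(new_state, params)
    spikes, _ = fire_and_reset(new_state.u, params)
    new_state.last_spike = spikes
    return new_state, spikes


def lif_step(state: MembraneState, synaptic_input: np.ndarray,
             params: NeuronParams):
    """Leaky integrate-and-fire step with hard reset to zero on spike."""
    synaptic_input = np.asarray(synaptic_input, dtype=np.float64)
    if synaptic_input.shape != state.u.shape:
        raise ValueError(
            f"input shape {synaptic_input.shape} != state shape {state.u.shape}")
    u_new = params.lif_decay * state.u * (1.0 - state.last_spike) + synaptic_input
    spikes, _ = fire_and_reset(u_new, params)
    new_state = MembraneState(u=u_new, m=state.m, n=state.n, h=state.h,
                              last_spike=spikes)
    return new_state, spikes


def surrogate_grad(u: np.ndarray, params: NeuronParams) -> np.ndarray:
    """Rectangular surrogate derivative of the spike function (backward only)."""
    _check_finite(u)
    return (np.abs(np.asarray(u) - params.v_th) < params.a1 / 2).astype(np.float64) / params.a1


class SpikingLayer:
    """Differentiable spiking population unrolled over simulation steps.

    Consumes stacked synaptic currents ``[T, ...]`` (or a per-step list)
    and emits hard binary spikes; the backward pass substitutes the
    rectangular surrogate everywhere the spike function appears,
    including in the reset pathway.  Gating is static here (the
    effective Na/K conductance factors are constants), matching the
    default dynamics above.  The whole recurrence is one tape node.
    """

    def __init__(self, params: NeuronParams, relaxed: bool = False):
        self.p = params
        self.relaxed = relaxed
        # frozen-gating effective conductances (m = h = 1, n = 0.5)
        self.c_na = params.g_na
        self.c_k = params.g_k * 0.5 ** 4

    def forward_stacked(self, currents: ag.Tensor) -> ag.Tensor:
        p = self.p
        if p.mode == "lif":
            return ag.spiking_recurrence(
                currents, mode="lif", lif_decay=p.lif_decay, v_th=p.v_th,
                a1=p.a1, relaxed=self.relaxed)
        k = p.dt / p.capacitance
        g_tot = self.c_na + self.c_k + p.g_l
        drive = self.c_na * p.e_na + self.c_k * p.e_k + p.g_l * p.e_l
        return ag.spiking_recurrence(
            currents, mode="rgc", leak=k * g_tot, gain=k, const=k * drive,
            v_th=p.v_th, a1=p.a1, relaxed=self.relaxed)

    def forward(self, currents):
        """Per-step list in, per-step list out (stacked path internally)."""
        if isinstance(currents, ag.Tensor):
            return self.forward_stacked(currents)
        out = self.forward_stacked(ag.stack_steps(list(currents)))
        return [ag.take_step(out, t) for t in range(len(currents))]
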