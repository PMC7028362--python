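"""Trace-based STDP with soft bounds at the KC->MBON synapse.

Each presynaptic (KC) spike increments a trace x that decays with time
constant tau_plus; each postsynaptic (MBON) spike increments a trace y
with tau_minus.  A postsynaptic spike potentiates every synapse by
``A_plus * x`` with ``A_plus = (W_max - w) * eta_plus``; a presynaptic
spike depresses by ``A_minus * y`` with ``A_minus = w * eta_minus``.  The
weight-dependent amplitudes (soft bounds) make depression dominate near
W_max and potentiation dominate near zero, so balanced pre/post activity
drives the weights towards a stable interior fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from locustolf.al_network import SpikeTable
from locustolf.mb_network import (
    MBConnectivity,
    MapNeuronParams,
    MapSynapseParams,
    MBON_SYNAPSE,
    _run_map_layer,
)

__all__ = [
    "STDPParams",
    "TraceState",
    "decay_traces",
    "on_pre_spike",
    "on_post_spike",
    "pair_delta_w",
    "WeightHistory",
    "train",
]


@dataclass(frozen=True)
class STDPParams:
    """STDP time constants, trace increments and soft-bound learning rates.

    Defaults put the balanced-pairing fixed point at W_max / 2: with
    a_plus = a_minus and eta_plus = eta_minus, symmetric pre/post pairing
    balances (W_max - w) eta_plus a_plus against w eta_minus a_minus at
    w = W_max / 2 = 1.
    """

    a_plus: float = 1.0
    a_minus: float = 1.0
    tau_plus: float = 20.0  # ms, within an oscillatory cycle
    tau_minus: float = 20.0  # ms
    eta_plus: float = 0.01
    eta_minus: float = 0.01
    w_max: float = 2.0
    w_min: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a_plus, self.a_minus, self.tau_plus, self.tau_minus) <= 0:
            raise ValueError("trace increments and time constants must be > 0")
        if min(self.eta_plus, self.eta_minus) <= 0:
            raise ValueError("learning rates must be > 0")
        if not 0 <= self.w_min < self.w_max:
            raise ValueError("need 0 <= w_min < w_max")

    @property
    def balanced_fixed_point(self) -> float:
        """w* where symmetric pairing balances potentiation and depression."""
        num = self.w_max * self.eta_plus * self.a_plus
        return num / (self.eta_plus * self.a_plus + self.eta_minus * self.a_minus)


@dataclass
class TraceState:
    """Presynaptic trace x and postsynaptic trace y (dimensionless)."""

    x: np.ndarray | float = 0.0
    y: np.ndarray | float = 0.0


def decay_traces(traces: TraceState, dt: float, params: STDPParams) -> TraceState:
    """Exponential decay of both traces over ``dt`` ms (exact)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return TraceState(
        x=traces.x * np.exp(-dt / params.tau_plus),
        y=traces.y * np.exp(-dt / params.tau_minus),
    )


def on_pre_spike(w, traces: TraceState, params: STDPParams):
    """Presynaptic spike: depress by ``w eta_minus y``, then bump x."""
    a_minus = np.asarray(w, dtype=float) * params.eta_minus
    w_new = np.clip(w - a_minus * traces.y, params.w_min, params.w_max)
    return w_new, TraceState(x=traces.x + params.a_plus, y=traces.y)


def on_post_spike(w, traces: TraceState, params: STDPParams):
    """Postsynaptic spike: potentiate by ``(W_max - w) eta_plus x``, bump y."""
    a_plus = (params.w_max - np.asarray(w, dtype=float)) * params.eta_plus
    w_new = np.clip(w + a_plus * traces.x, params.w_min, params.w_max)
    return w_new, TraceState(x=traces.x, y=traces.y + params.a_minus)


def pair_delta_w(w: float, delta_t: float, params: STDPParams) -> float:
    """Closed-form weight change for a single isolated pre/post spike pair.

    ``delta_t = t_post - t_pre``; positive means pre-before-post
    (potentiation), negative post-before-pre (depression).
    """
    if delta_t >= 0:
        return float((params.w_max - w) * params.eta_plus * params.a_plus * np.exp(-delta_t / params.tau_plus))
    return float(-w * params.eta_minus * params.a_minus * np.exp(delta_t / params.tau_minus))


@dataclass
class WeightHistory:
    """Weight snapshots over training plus the median of changed synapses."""

    times: list[float] = field(default_factory=list)
    snapshots: list[np.ndarray] = field(default_factory=list)  # on-mask weights
    changed_mask: np.ndarray | None = None  # within the on-mask vector

    @property
    def median_trajectory(self) -> np.ndarray:
        """Median over the synapses that changed during training."""
        if not self.snapshots:
            return np.array([])
        mask = self.changed_mask
        if mask is None or not mask.any():
            mask = np.ones_like(self.snapshots[0], dtype=bool)
        return np.array([np.median(s[mask]) for s in self.snapshots])


def run_mbon_layer_plastic(
    kc_spikes: SpikeTable,
    connectivity: MBConnectivity,
    stdp: STDPParams,
    neuron: MapNeuronParams = MapNeuronParams(),
    synapse: MapSynapseParams = MBON_SYNAPSE,
    duration: float | None = None,
    traces: TraceState | None = None,
) -> tuple[SpikeTable, np.ndarray, TraceState]:
    """One trial of the MBON layer with online STDP.

    Traces decay once per map iteration; on each presynaptic KC spike the
    incoming columns are depressed through the postsynaptic y traces, on
    each MBON spike its row is potentiated through the presynaptic x
    traces.  Within one iteration presynaptic updates are applied first,
    so coincident pairs count as pre-before-post.  Returns the MBON spike
    table, the updated weight matrix and the final traces.
    """
    if duration is None:
        duration = kc_spikes.duration
    w = connectivity.weights.copy()
    mask = connectivity.kc_mbon_mask
    x = np.zeros(connectivity.n_kc)
    y = np.zeros(connectivity.n_mbon)
    if traces is not None:
        x = x + traces.x
        y = y + traces.y
    dx = np.exp(-neuron.ms_per_iter / stdp.tau_plus)
    dy = np.exp(-neuron.ms_per_iter / stdp.tau_minus)

    def pre_hook(pre_ids):
        cols = w[:, pre_ids]
        m = mask[:, pre_ids]
        cols -= np.where(m, cols * stdp.eta_minus * y[:, None], 0.0)
        w[:, pre_ids] = np.clip(cols, stdp.w_min, stdp.w_max)
        np.add.at(x, pre_ids, stdp.a_plus)

    def post_hook(post_ids):
        rows = w[post_ids, :]
        m = mask[post_ids, :]
        rows += np.where(m, (stdp.w_max - rows) * stdp.eta_plus * x[None, :], 0.0)
        w[post_ids, :] = np.clip(rows, stdp.w_min, stdp.w_max)
        y[post_ids] += stdp.a_minus

    def iter_hook(_n):
        np.multiply(x, dx, out=x)
        np.multiply(y, dy, out=y)

    # the layer reads w in place, so plastic changes act within the trial
    spikes = _run_map_layer(
        kc_spikes,
        w,
        neuron,
        synapse,
        duration,
        population="MBON",
        on_pre_spikes=pre_hook,
        on_post_spikes=post_hook,
        on_iteration=iter_hook,
    )
    w[~mask] = 0.0
    return spikes, w, TraceState(x=x, y=y)


def train(
    connectivity: MBConnectivity,
    kc_spike_trials: list[SpikeTable],
    stdp: STDPParams = STDPParams(),
    neuron: MapNeuronParams = MapNeuronParams(),
    synapse: MapSynapseParams = MBON_SYNAPSE,
    snapshot_every: int = 5,
    change_tol: float = 1e-9,
) -> tuple[MBConnectivity, WeightHistory]:
    """Train the KC->MBON weights on a sequence of KC response trials.

    Traces are reset between presentations (inter-trial intervals are long
    relative to the trace time constants).  Weight snapshots are taken
    every ``snapshot_every`` presentations; the median trajectory is
    computed over the subset of synapses that changed at all during
    training (sparse KC activity leaves most weights untouched).
    """
    if not kc_spike_trials:
        raise ValueError("empty training schedule")
    mask = connectivity.kc_mbon_mask
    history = WeightHistory()
    w0 = connectivity.weights[mask].copy()
    history.times.append(0.0)
    history.snapshots.append(w0.copy())
    conn = connectivity
    sim_time = 0.0
    for i, trial in enumerate(kc_spike_trials):
        _, w_new, _ = run_mbon_layer_plastic(
            trial, conn, stdp, neuron=neuron, synapse=synapse
        )
        conn = conn.with_weights(w_new)
        sim_time += trial.duration
        if (i + 1) % snapshot_every == 0 or i == len(kc_spike_trials) - 1:
            history.times.append(sim_time)
            history.snapshots.append(conn.weights[mask].copy())
    history.changed_mask = np.abs(history.snapshots[-1] - w0) > change_tol
    return conn, history
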