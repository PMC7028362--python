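"""Conductance-based antennal lobe network.

Single-compartment projection neurons (PNs, Na spikes) and inhibitory
local neurons (LNs, Ca spikelets with Ca-dependent K adaptation) with
Hodgkin-Huxley-style kinetics, coupled by fast GABAergic (LN->PN, LN->LN)
and nicotinic cholinergic (PN->LN and a subset of PN->PN) synapses.

Units: mV, ms, uS, nA; membrane capacitance is held in uF so that
dV/dt = I[nA] / (1000 * Cm[uF]) is in mV/ms.  Integration uses
exponential-Euler updates for the membrane potential, every gating
variable, intracellular calcium and the synaptic open fractions: each of
these is locally linear in its own state, so the update is unconditionally
stable despite the stiff sodium conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PNParams",
    "LNParams",
    "SynapseKinetics",
    "SynapseState",
    "GABA_KINETICS",
    "NACH_KINETICS",
    "ALConfig",
    "ALNetwork",
    "ALTrajectory",
    "SpikeTable",
    "steady_state_gates",
    "ionic_current",
    "update_calcium",
    "update_synapse",
    "transmitter",
    "build_al_network",
    "integrate_al",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class PNParams:
    """Projection-neuron membrane parameters (uS, mV, uF)."""

    cm: float = 1.43e-4
    g_l: float = 0.15
    e_l: float = -55.0
    g_kl: float = 0.05
    e_kl: float = -95.0
    g_na: float = 50.0
    e_na: float = 50.0
    g_k: float = 10.0
    e_k: float = -95.0
    g_a: float = 10.0
    # The A-current is a potassium current; its reversal follows E_K.
    e_a: float = -95.0

    def __post_init__(self) -> None:
        _check_conductances(self)


@dataclass(frozen=True)
class LNParams:
    """Local-neuron membrane parameters, with Ca and K(Ca) currents."""

    cm: float = 1.43e-4
    g_l: float = 0.15
    e_l: float = -55.0
    g_kl: float = 0.05
    e_kl: float = -95.0
    g_k: float = 10.0
    e_k: float = -95.0
    g_ca: float = 2.0
    e_ca: float = 140.0
    g_kca: float = 1.2
    e_kca: float = -90.0
    a_ca: float = 5.2e-4  # mM cm^2 / (uA ms): converts Ca current *density*
    area_cm2: float = 1.43e-4  # cell area implied by Cm at 1 uF/cm^2
    tau_ca: float = 5.0  # ms
    ca_inf: float = 2.4e-4  # mM

    def __post_init__(self) -> None:
        _check_conductances(self)


def _check_conductances(p) -> None:
    for name, value in vars(p).items():
        if name.startswith("g_") and value < 0:
            raise ValueError(f"conductance {name} must be >= 0")
        if name.startswith("e_") and not -120.0 <= value <= 150.0:
            raise ValueError(f"reversal {name} outside [-120, 150] mV")


@dataclass(frozen=True)
class SynapseKinetics:
    """First-order kinetic synapse: d[O]/dt = alpha (1-[O]) [T] - beta [O]."""

    alpha: float  # 1/ms
    beta: float  # 1/ms
    e_syn: float  # mV
    # nACh transmitter: square pulse of amplitude a_t lasting t_max after a
    # presynaptic spike.  GABA transmitter: sigmoid of presynaptic voltage.
    kind: str = "nach"
    a_t: float = 0.5
    t_max: float = 0.3  # ms
    v0: float = -20.0  # mV, GABA release half-activation
    sigma_t: float = 1.5  # mV, GABA release slope


NACH_KINETICS = SynapseKinetics(alpha=10.0, beta=0.2, e_syn=0.0, kind="nach")
GABA_KINETICS = SynapseKinetics(alpha=10.0, beta=0.16, e_syn=-70.0, kind="gaba")


@dataclass
class SynapseState:
    """Open fraction plus kinetics for a single synapse population."""

    o: float = 0.0
    kinetics: SynapseKinetics = NACH_KINETICS
    g_syn: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.o <= 1.0:
            raise ValueError("open fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# gating kinetics

_GATE_IDS = ("Na_m", "Na_h", "K_n", "A_m", "A_h", "Ca_m", "Ca_h", "KCa_m")


def _vtrap(x, scale):
    """x / (exp(x/scale) - 1) with the analytic limit `scale` at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7 * scale
    safe = np.where(small, 1.0, x)
    out = np.where(small, scale - x / 2.0, safe / np.expm1(safe / scale))
    return out


def steady_state_gates(v, current_id: str):
    """Steady state ``x_inf`` and time constant ``tau_x`` (ms) of one gate.

    ``v`` is the membrane potential in mV, except for ``KCa_m`` where the
    controlling variable is the intracellular calcium concentration in mM.
    Rate-based gates (Na, K) return alpha/(alpha+beta) and 1/(alpha+beta);
    removable singularities in the rate expressions are evaluated by their
    analytic limits.
    """
    v = np.asarray(v, dtype=float)
    if current_id == "Na_m":
        # Traub kinetics on the shifted voltage V2 = V + 55 (the printed h
        # rates carry this shift; the literal "13 - V" in the activation
        # rate reads as 13 - V2, i.e. -(V + 42)).
        alpha = 0.32 * _vtrap(-(v + 42.0), 4.0)
        beta = 0.28 * _vtrap(v + 15.0, 5.0)
        return alpha / (alpha + beta), 1.0 / (alpha + beta)
    if current_id == "Na_h":
        alpha = 0.128 * np.exp(-(38.0 + v) / 18.0)
        beta = 4.0 / (1.0 + np.exp(-(15.0 + v) / 5.0))
        return alpha / (alpha + beta), 1.0 / (alpha + beta)
    if current_id == "K_n":
        alpha = 0.02 * _vtrap(-(30.0 + v), 5.0)
        beta = 0.5 * np.exp(-(35.0 + v) / 40.0)
        return alpha / (alpha + beta), 1.0 / (alpha + beta)
    if current_id == "A_m":
        x_inf = 1.0 / (1.0 + np.exp(-(v + 60.0) / 8.5))
        tau = 1.0 / (np.exp((v + 35.8) / 19.7) + np.exp(-(v + 79.7) / 12.7))
        return x_inf, tau
    if current_id == "A_h":
        x_inf = 1.0 / (1.0 + np.exp((v + 78.0) / 6.0))
        tau = 1.0 / (np.exp((v + 46.0) / 5.0) + np.exp(-(v + 238.4) / 37.45))
        return x_inf, tau
    if current_id == "Ca_m":
        x_inf = 1.0 / (1.0 + np.exp(-(v + 20.0) / 6.5))
        return x_inf, np.full_like(v, 1.5) if v.ndim else 1.5
    if current_id == "Ca_h":
        x_inf = 1.0 / (1.0 + np.exp((v + 25.0) / 12.0))
        tau = 0.3 * np.exp((v - 40.0) / 13.0) + 0.002 * np.exp(-(v - 60.0) / 29.0)
        return x_inf, tau
    if current_id == "KCa_m":
        ca = v  # controlling variable is [Ca2+] in mM
        x_inf = ca / (ca + 2.0)
        tau = 100.0 / (ca + 2.0)
        return x_inf, tau
    raise ValueError(f"unknown current_id {current_id!r}; expected one of {_GATE_IDS}")


def ionic_current(current_id: str, v, gates, params):
    """Instantaneous ionic current (nA) given gate values.

    ``gates`` is a mapping with the keys needed by the current: ``m``/``h``
    for Na, Ca and A, ``n`` for K, ``m`` for KCa.
    """
    if current_id == "Na":
        return params.g_na * gates["m"] ** 3 * gates["h"] * (v - params.e_na)
    if current_id == "K":
        return params.g_k * gates["n"] ** 4 * (v - params.e_k)
    if current_id == "A":
        return params.g_a * gates["m"] ** 4 * gates["h"] * (v - params.e_a)
    if current_id == "Ca":
        return params.g_ca * gates["m"] ** 2 * gates["h"] * (v - params.e_ca)
    if current_id == "KCa":
        return params.g_kca * gates["m"] * (v - params.e_kca)
    raise ValueError(f"unknown current_id {current_id!r}")


def update_calcium(ca, i_ca, dt: float, params: LNParams = LNParams()):
    """Advance [Ca2+] by ``dt`` under d[Ca]/dt = -A*I_Ca - ([Ca]-[Ca]inf)/tau.

    Exact exponential update of the linear relaxation; inward (negative)
    calcium current raises the concentration.  The result is floored at a
    tiny positive value to preserve [Ca2+] > 0.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    # A has per-area units: it converts the Ca current *density* in uA/cm^2
    # (i_ca is in nA for the whole cell) into mM/ms.
    i_density = np.asarray(i_ca, dtype=float) * 1e-3 / params.area_cm2
    target = params.ca_inf - params.a_ca * params.tau_ca * i_density
    ca_next = target + (np.asarray(ca, dtype=float) - target) * np.exp(-dt / params.tau_ca)
    return np.maximum(ca_next, 1e-12)


def transmitter(kinetics: SynapseKinetics, v_pre=None, t_since_pre_spike=None):
    """Transmitter concentration [T] seen by the receptor.

    nACh: square pulse ``a_t`` for 0 <= t_since_pre_spike < t_max, else 0.
    GABA: sigmoid of the presynaptic voltage (graded release).
    """
    if kinetics.kind == "nach":
        t = np.asarray(t_since_pre_spike, dtype=float)
        return np.where((t >= 0.0) & (t < kinetics.t_max), kinetics.a_t, 0.0)
    if kinetics.kind == "gaba":
        v = np.asarray(v_pre, dtype=float)
        return 1.0 / (1.0 + np.exp(-(v - kinetics.v0) / kinetics.sigma_t))
    raise ValueError(f"unknown synapse kind {kinetics.kind!r}")


def _open_fraction_step(o, t_conc, kin: SynapseKinetics, dt: float):
    """Exponential update of d[O]/dt = alpha (1-[O]) [T] - beta [O]."""
    rate = kin.alpha * t_conc + kin.beta
    o_inf = kin.alpha * t_conc / rate
    return o_inf + (o - o_inf) * np.exp(-rate * dt)


def update_synapse(
    state: SynapseState,
    v_pre: float | None = None,
    t_since_pre_spike: float | None = None,
    dt: float = 0.02,
) -> SynapseState:
    """Advance a single synapse's open fraction by one step of ``dt`` ms."""
    t_conc = transmitter(state.kinetics, v_pre=v_pre, t_since_pre_spike=t_since_pre_spike)
    o_next = float(_open_fraction_step(state.o, t_conc, state.kinetics, dt))
    return replace(state, o=min(max(o_next, 0.0), 1.0))


# ---------------------------------------------------------------------------
# network


@dataclass(frozen=True)
class ALConfig:
    """Sizes, connection probabilities and synaptic strengths of the AL.

    Per-type synaptic strengths are *total* conductances per postsynaptic
    neuron (uS); the per-connection conductance is the total divided by the
    expected presynaptic fan-in, so behaviour is comparable across network
    scales.
    """

    n_pn: int = 350
    n_ln: int = 100
    n_exc_pn: int = 50
    p_pn_ln: float = 0.5
    p_ln_pn: float = 0.5
    p_ln_ln: float = 0.5
    p_pn_pn: float = 0.5
    g_pn_ln: float = 0.15  # nACh, total uS onto each LN
    g_ln_pn: float = 1.5  # GABA_A, total uS onto each PN
    g_ln_ln: float = 0.3  # GABA_A, total uS onto each LN
    g_pn_pn: float = 0.1  # nACh from the excitatory PN subset onto each PN
    pn_params: PNParams = PNParams()
    ln_params: LNParams = LNParams()
    nach: SynapseKinetics = NACH_KINETICS
    gaba: SynapseKinetics = GABA_KINETICS
    pn_spike_threshold: float = -20.0
    ln_spike_threshold: float = -40.0
    pn_refractory_ms: float = 2.0
    ln_refractory_ms: float = 5.0

    def __post_init__(self) -> None:
        if min(self.n_pn, self.n_ln) < 1:
            raise ValueError("population sizes must be >= 1")
        for name in ("p_pn_ln", "p_ln_pn", "p_ln_ln", "p_pn_pn"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_exc_pn > self.n_pn:
            raise ValueError("n_exc_pn cannot exceed n_pn")


@dataclass(frozen=True)
class ALNetwork:
    """Antennal-lobe connectivity sampled from an :class:`ALConfig`.

    Adjacency matrices are boolean, oriented (n_post, n_pre) so that the
    conductance arriving at each postsynaptic neuron is a matrix product
    with the presynaptic open-fraction vector.
    """

    config: ALConfig
    seed: int
    a_pn_ln: np.ndarray  # (n_ln, n_pn) cholinergic
    a_ln_pn: np.ndarray  # (n_pn, n_ln) GABAergic
    a_ln_ln: np.ndarray  # (n_ln, n_ln) GABAergic, no self-connections
    a_pn_pn: np.ndarray  # (n_pn, n_pn) cholinergic, from exc_pn_idx columns only
    exc_pn_idx: np.ndarray  # indices of the PNs that excite other PNs

    @property
    def n_pn(self) -> int:
        return self.config.n_pn

    @property
    def n_ln(self) -> int:
        return self.config.n_ln

    def unit_conductances(self):
        """Per-connection conductances (uS), normalised by expected fan-in."""
        c = self.config
        return {
            "pn_ln": c.g_pn_ln / max(c.p_pn_ln * c.n_pn, 1.0),
            "ln_pn": c.g_ln_pn / max(c.p_ln_pn * c.n_ln, 1.0),
            "ln_ln": c.g_ln_ln / max(c.p_ln_ln * (c.n_ln - 1), 1.0),
            "pn_pn": c.g_pn_pn / max(c.p_pn_pn * c.n_exc_pn, 1.0),
        }


def build_al_network(config: ALConfig, seed: int) -> ALNetwork:
    """Sample AL connectivity reproducibly from ``seed``.

    Each potential connection is an independent Bernoulli draw; only the
    configured excitatory PN subset sends PN->PN connections, and no neuron
    connects to itself.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    c = config
    a_pn_ln = rng.random((c.n_ln, c.n_pn)) < c.p_pn_ln
    a_ln_pn = rng.random((c.n_pn, c.n_ln)) < c.p_ln_pn
    a_ln_ln = rng.random((c.n_ln, c.n_ln)) < c.p_ln_ln
    np.fill_diagonal(a_ln_ln, False)
    exc_pn_idx = np.sort(rng.choice(c.n_pn, size=c.n_exc_pn, replace=False))
    a_pn_pn = np.zeros((c.n_pn, c.n_pn), dtype=bool)
    a_pn_pn[:, exc_pn_idx] = rng.random((c.n_pn, c.n_exc_pn)) < c.p_pn_pn
    np.fill_diagonal(a_pn_pn, False)
    return ALNetwork(
        config=c,
        seed=seed,
        a_pn_ln=a_pn_ln,
        a_ln_pn=a_ln_pn,
        a_ln_ln=a_ln_ln,
        a_pn_pn=a_pn_pn,
        exc_pn_idx=exc_pn_idx,
    )


# ---------------------------------------------------------------------------
# spike tables and trajectories


@dataclass(frozen=True)
class SpikeTable:
    """Spike events of one population: parallel (neuron_id, t_ms) arrays."""

    neuron_ids: np.ndarray
    times: np.ndarray
    population: str
    n_neurons: int
    duration: float

    def __post_init__(self) -> None:
        ids = np.asarray(self.neuron_ids, dtype=np.int64)
        t = np.asarray(self.times, dtype=float)
        if ids.shape != t.shape:
            raise ValueError("neuron_ids and times must have the same length")
        order = np.argsort(t, kind="stable")
        object.__setattr__(self, "neuron_ids", ids[order])
        object.__setattr__(self, "times", t[order])
        if len(t) and (t.min() < 0 or t.max() > self.duration):
            raise ValueError("spike times outside [0, duration]")
        if len(ids) and ids.max() >= self.n_neurons:
            raise ValueError("neuron_id exceeds population size")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population": self.population,
                "neuron_id": self.neuron_ids,
                "t_ms": np.round(self.times, 4),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def from_csv(cls, path: str | Path, n_neurons: int, duration: float) -> "SpikeTable":
        df = pd.read_csv(path)
        pop = str(df["population"].iloc[0]) if len(df) else ""
        return cls(
            neuron_ids=df["neuron_id"].to_numpy(),
            times=df["t_ms"].to_numpy(),
            population=pop,
            n_neurons=n_neurons,
            duration=duration,
        )

    def spikes_of(self, neuron_id: int) -> np.ndarray:
        return self.times[self.neuron_ids == neuron_id]


@dataclass(frozen=True)
class ALTrajectory:
    """Result of one antennal-lobe trial.

    Always carries the LFP (mean PN membrane potential, one sample per
    integration step) and the PN/LN spike tables; full voltage traces are
    stored (decimated by ``v_stride`` steps) only when requested.
    """

    dt: float
    duration: float
    lfp: np.ndarray
    pn_spikes: SpikeTable
    ln_spikes: SpikeTable
    v_pn: np.ndarray | None = None
    v_ln: np.ndarray | None = None
    v_stride: int = 1

    @property
    def v_times(self) -> np.ndarray:
        n = len(self.v_pn) if self.v_pn is not None else len(self.lfp)
        return np.arange(n) * self.dt * (self.v_stride if self.v_pn is not None else 1)


class NumericalDivergenceError(RuntimeError):
    """Raised when the membrane potential leaves the physical range."""


# ---------------------------------------------------------------------------
# integration


def _exp_gate_update(gate, v, current_id, dt):
    x_inf, tau = steady_state_gates(v, current_id)
    return x_inf + (gate - x_inf) * np.exp(-dt / tau)


def integrate_al(
    network: ALNetwork,
    stim,
    duration: float | None = None,
    dt: float = 0.02,
    seed: int | None = None,
    store_v: bool = False,
    v_stride: int = 25,
    backend: str = "auto",
) -> ALTrajectory:
    """Integrate the antennal lobe over one stimulus trial.

    Parameters
    ----------
    network : ALNetwork
    stim : StimulusTrial or None
        Per-neuron input amplitudes and envelope.  ``None`` means no input.
    duration : float, optional
        Trial length in ms; defaults to the stimulus envelope plus two
        decay e-folds (1460 ms for the default protocol).
    dt : float
        Integration step, ms.  Must be <= 0.04 for accurate spike shapes.
    seed : int, optional
        Seed of the input-noise stream; defaults to ``stim.seed``.
    store_v : bool
        Keep the full (decimated) voltage matrices in the result.
    backend : str
        "numba" (compiled chunked kernel), "numpy" (reference loop), or
        "auto" (numba when available).  Both backends implement the same
        update scheme; "numpy" additionally supports ``store_v``.
    """
    from locustolf import _kernel

    if backend == "auto":
        backend = "numba" if (_kernel.HAVE_NUMBA and not store_v) else "numpy"
    if backend == "numba":
        return _integrate_kernel(network, stim, duration, dt, seed)
    if backend != "numpy":
        raise ValueError("backend must be 'auto', 'numba' or 'numpy'")
    return _integrate_numpy(network, stim, duration, dt, seed, store_v, v_stride)


def _setup_inputs(network, stim, duration, dt, seed):
    c = network.config
    if duration is None:
        duration = stim.protocol.total_ms() if stim is not None else 500.0
    n_steps = int(round(duration / dt))
    if stim is not None:
        pn_amp = np.asarray(stim.pn_amplitudes, dtype=float)
        ln_amp = np.asarray(stim.ln_amplitudes, dtype=float)
        if pn_amp.shape != (c.n_pn,) or ln_amp.shape != (c.n_ln,):
            raise ValueError("stimulus amplitude vectors do not match network size")
        env = stim.envelope(np.arange(n_steps) * dt)
        noise_frac = stim.protocol.noise_frac
        rng = np.random.default_rng(seed if seed is not None else stim.seed)
    else:
        pn_amp = np.zeros(c.n_pn)
        ln_amp = np.zeros(c.n_ln)
        env = np.zeros(n_steps)
        noise_frac = 0.0
        rng = np.random.default_rng(seed)
    return duration, n_steps, pn_amp, ln_amp, env, noise_frac, rng


def _initial_state(network):
    c = network.config
    pn, ln = c.pn_params, c.ln_params
    v_pn = np.full(c.n_pn, pn.e_l)
    v_ln = np.full(c.n_ln, ln.e_l)
    ca_conc = np.full(c.n_ln, ln.ca_inf)
    state = {
        "v_pn": v_pn,
        "na_m": steady_state_gates(v_pn, "Na_m")[0].copy(),
        "na_h": steady_state_gates(v_pn, "Na_h")[0].copy(),
        "k_n_pn": steady_state_gates(v_pn, "K_n")[0].copy(),
        "a_m": steady_state_gates(v_pn, "A_m")[0].copy(),
        "a_h": steady_state_gates(v_pn, "A_h")[0].copy(),
        "o_ach": np.zeros(c.n_pn),
        "last_pn_spike": np.full(c.n_pn, -1e9),
        "v_ln": v_ln,
        "ca_m": steady_state_gates(v_ln, "Ca_m")[0].copy(),
        "ca_h": steady_state_gates(v_ln, "Ca_h")[0].copy(),
        "k_n_ln": steady_state_gates(v_ln, "K_n")[0].copy(),
        "ca_conc": ca_conc,
        "kca_m": steady_state_gates(ca_conc, "KCa_m")[0].copy(),
        "o_gaba": np.zeros(c.n_ln),
        "last_ln_spike": np.full(c.n_ln, -1e9),
    }
    return state


def _weighted_adjacency(network):
    gu = network.unit_conductances()
    return {
        "w_pn_ln": np.ascontiguousarray(network.a_pn_ln * gu["pn_ln"]),
        "w_ln_pn": np.ascontiguousarray(network.a_ln_pn * gu["ln_pn"]),
        "w_ln_ln": np.ascontiguousarray(network.a_ln_ln * gu["ln_ln"]),
        "w_pn_pn": np.ascontiguousarray(network.a_pn_pn * gu["pn_pn"]),
    }


def _spike_table(ids, ts, pop, size, duration):
    if len(ids):
        return SpikeTable(np.concatenate(ids), np.concatenate(ts), pop, size, duration)
    return SpikeTable(np.array([], dtype=int), np.array([]), pop, size, duration)


def _integrate_kernel(network, stim, duration, dt, seed):
    from locustolf._kernel import step_chunk

    if dt <= 0 or dt > 0.04:
        raise ValueError("dt must be in (0, 0.04] ms")
    c = network.config
    pn, ln = c.pn_params, c.ln_params
    nach, gaba = c.nach, c.gaba
    duration, n_steps, pn_amp, ln_amp, env, noise_frac, rng = _setup_inputs(
        network, stim, duration, dt, seed
    )
    st = _initial_state(network)
    w = _weighted_adjacency(network)
    lfp = np.empty(n_steps)
    pn_ids, pn_ts, ln_ids, ln_ts = [], [], [], []
    chunk = 2000
    cap_pn = (int(chunk * dt / c.pn_refractory_ms) + 2) * c.n_pn
    cap_ln = (int(chunk * dt / c.ln_refractory_ms) + 2) * c.n_ln
    buf_pn_id = np.empty(cap_pn, dtype=np.int64)
    buf_pn_t = np.empty(cap_pn)
    buf_ln_id = np.empty(cap_ln, dtype=np.int64)
    buf_ln_t = np.empty(cap_ln)
    empty = np.zeros((1, 1))
    for start in range(0, n_steps, chunk):
        n_chunk = min(chunk, n_steps - start)
        if noise_frac:
            noise_pn = rng.standard_normal((n_chunk, c.n_pn))
            noise_ln = rng.standard_normal((n_chunk, c.n_ln))
        else:
            noise_pn = noise_ln = empty
        n_spk_pn, n_spk_ln = step_chunk(
            n_chunk, start * dt, dt,
            st["v_pn"], st["na_m"], st["na_h"], st["k_n_pn"], st["a_m"], st["a_h"],
            st["o_ach"], st["last_pn_spike"],
            st["v_ln"], st["ca_m"], st["ca_h"], st["k_n_ln"], st["ca_conc"],
            st["kca_m"], st["o_gaba"], st["last_ln_spike"],
            w["w_ln_pn"], w["w_pn_pn"], w["w_pn_ln"], w["w_ln_ln"],
            env[start : start + n_chunk], pn_amp, ln_amp, noise_pn, noise_ln,
            float(noise_frac),
            pn.cm * 1e3, pn.g_l, pn.e_l, pn.g_kl, pn.e_kl, pn.g_na, pn.e_na,
            pn.g_k, pn.e_k, pn.g_a, pn.e_a,
            ln.cm * 1e3, ln.g_l, ln.e_l, ln.g_kl, ln.e_kl, ln.g_k, ln.e_k,
            ln.g_ca, ln.e_ca, ln.g_kca, ln.e_kca, ln.a_ca, ln.area_cm2,
            ln.tau_ca, ln.ca_inf,
            nach.alpha, nach.beta, nach.e_syn, nach.a_t, nach.t_max,
            gaba.alpha, gaba.beta, gaba.e_syn, gaba.v0, gaba.sigma_t,
            c.pn_spike_threshold, c.ln_spike_threshold,
            c.pn_refractory_ms, c.ln_refractory_ms,
            lfp[start : start + n_chunk],
            buf_pn_id, buf_pn_t, buf_ln_id, buf_ln_t,
        )
        if n_spk_pn:
            pn_ids.append(buf_pn_id[:n_spk_pn].copy())
            pn_ts.append(buf_pn_t[:n_spk_pn].copy())
        if n_spk_ln:
            ln_ids.append(buf_ln_id[:n_spk_ln].copy())
            ln_ts.append(buf_ln_t[:n_spk_ln].copy())
        last = lfp[start + n_chunk - 1]
        if abs(last) > 200.0 or not np.isfinite(last):
            raise NumericalDivergenceError(
                f"membrane potential diverged near t = {(start + n_chunk) * dt:.2f} ms"
            )
    return ALTrajectory(
        dt=dt,
        duration=duration,
        lfp=lfp,
        pn_spikes=_spike_table(pn_ids, pn_ts, "PN", c.n_pn, duration),
        ln_spikes=_spike_table(ln_ids, ln_ts, "LN", c.n_ln, duration),
    )


def _integrate_numpy(
    network: ALNetwork,
    stim,
    duration: float | None = None,
    dt: float = 0.02,
    seed: int | None = None,
    store_v: bool = False,
    v_stride: int = 25,
) -> ALTrajectory:
    if dt <= 0 or dt > 0.04:
        raise ValueError("dt must be in (0, 0.04] ms")
    c = network.config
    pn, ln = c.pn_params, c.ln_params
    nach, gaba = c.nach, c.gaba
    if duration is None:
        duration = stim.protocol.total_ms() if stim is not None else 500.0
    n_steps = int(round(duration / dt))

    if stim is not None:
        pn_amp = np.asarray(stim.pn_amplitudes, dtype=float)
        ln_amp = np.asarray(stim.ln_amplitudes, dtype=float)
        if pn_amp.shape != (c.n_pn,) or ln_amp.shape != (c.n_ln,):
            raise ValueError("stimulus amplitude vectors do not match network size")
        env = stim.envelope(np.arange(n_steps) * dt)
        noise_frac = stim.protocol.noise_frac
        rng = np.random.default_rng(seed if seed is not None else stim.seed)
    else:
        pn_amp = np.zeros(c.n_pn)
        ln_amp = np.zeros(c.n_ln)
        env = np.zeros(n_steps)
        noise_frac = 0.0
        rng = np.random.default_rng(seed)

    gu = network.unit_conductances()
    # weighted adjacency, float for fast matmul with open-fraction vectors
    w_pn_ln = network.a_pn_ln * gu["pn_ln"]
    w_ln_pn = network.a_ln_pn * gu["ln_pn"]
    w_ln_ln = network.a_ln_ln * gu["ln_ln"]
    w_pn_pn = network.a_pn_pn * gu["pn_pn"]

    # state: PN gates (Na m/h, K n, A m/h), LN gates (Ca m/h, K n, KCa m, [Ca])
    v_pn = np.full(c.n_pn, pn.e_l)
    v_ln = np.full(c.n_ln, ln.e_l)
    na_m, _ = steady_state_gates(v_pn, "Na_m")
    na_m = na_m.copy()
    na_h = steady_state_gates(v_pn, "Na_h")[0].copy()
    k_n_pn = steady_state_gates(v_pn, "K_n")[0].copy()
    a_m = steady_state_gates(v_pn, "A_m")[0].copy()
    a_h = steady_state_gates(v_pn, "A_h")[0].copy()
    ca_m = steady_state_gates(v_ln, "Ca_m")[0].copy()
    ca_h = steady_state_gates(v_ln, "Ca_h")[0].copy()
    k_n_ln = steady_state_gates(v_ln, "K_n")[0].copy()
    ca_conc = np.full(c.n_ln, ln.ca_inf)
    kca_m = steady_state_gates(ca_conc, "KCa_m")[0].copy()
    o_ach = np.zeros(c.n_pn)  # one open fraction per presynaptic PN
    o_gaba = np.zeros(c.n_ln)  # one per presynaptic LN
    last_pn_spike = np.full(c.n_pn, -np.inf)
    last_ln_spike = np.full(c.n_ln, -np.inf)

    lfp = np.empty(n_steps)
    pn_ids: list[np.ndarray] = []
    pn_ts: list[np.ndarray] = []
    ln_ids: list[np.ndarray] = []
    ln_ts: list[np.ndarray] = []
    if store_v:
        n_rec = (n_steps + v_stride - 1) // v_stride
        rec_pn = np.empty((n_rec, c.n_pn))
        rec_ln = np.empty((n_rec, c.n_ln))

    cm_pn = pn.cm * 1e3  # nF
    cm_ln = ln.cm * 1e3
    chunk = 2000
    noise_pn = noise_ln = None
    for n in range(n_steps):
        t = n * dt
        if noise_frac and n % chunk == 0:
            noise_pn = rng.standard_normal((min(chunk, n_steps - n), c.n_pn))
            noise_ln = rng.standard_normal((min(chunk, n_steps - n), c.n_ln))

        # --- gating variables (exponential relaxation to steady state)
        na_m = _exp_gate_update(na_m, v_pn, "Na_m", dt)
        na_h = _exp_gate_update(na_h, v_pn, "Na_h", dt)
        k_n_pn = _exp_gate_update(k_n_pn, v_pn, "K_n", dt)
        a_m = _exp_gate_update(a_m, v_pn, "A_m", dt)
        a_h = _exp_gate_update(a_h, v_pn, "A_h", dt)
        ca_m = _exp_gate_update(ca_m, v_ln, "Ca_m", dt)
        ca_h = _exp_gate_update(ca_h, v_ln, "Ca_h", dt)
        k_n_ln = _exp_gate_update(k_n_ln, v_ln, "K_n", dt)
        i_ca = ln.g_ca * ca_m**2 * ca_h * (v_ln - ln.e_ca)
        ca_conc = update_calcium(ca_conc, i_ca, dt, ln)
        kca_m = _exp_gate_update(kca_m, ca_conc, "KCa_m", dt)

        # --- synaptic open fractions (per presynaptic neuron)
        t_ach = np.where((t - last_pn_spike) < nach.t_max, nach.a_t, 0.0)
        o_ach = _open_fraction_step(o_ach, t_ach, nach, dt)
        t_gaba = 1.0 / (1.0 + np.exp(-(v_ln - gaba.v0) / gaba.sigma_t))
        o_gaba = _open_fraction_step(o_gaba, t_gaba, gaba, dt)

        # --- conductance seen by each postsynaptic neuron
        g_gaba_pn = w_ln_pn @ o_gaba
        g_ach_pn = w_pn_pn @ o_ach
        g_ach_ln = w_pn_ln @ o_ach
        g_gaba_ln = w_ln_ln @ o_gaba

        # --- external input
        i_ext_pn = pn_amp * env[n]
        i_ext_ln = ln_amp * env[n]
        if noise_frac:
            i_ext_pn = i_ext_pn * (1.0 + noise_frac * noise_pn[n % chunk])
            i_ext_ln = i_ext_ln * (1.0 + noise_frac * noise_ln[n % chunk])

        # --- membrane potential (exponential update of the linearised ODE)
        g_na_eff = pn.g_na * na_m**3 * na_h
        g_k_eff = pn.g_k * k_n_pn**4
        g_a_eff = pn.g_a * a_m**4 * a_h
        g_tot = pn.g_l + pn.g_kl + g_na_eff + g_k_eff + g_a_eff + g_gaba_pn + g_ach_pn
        i_rev = (
            pn.g_l * pn.e_l
            + pn.g_kl * pn.e_kl
            + g_na_eff * pn.e_na
            + g_k_eff * pn.e_k
            + g_a_eff * pn.e_a
            + g_gaba_pn * gaba.e_syn
            + g_ach_pn * nach.e_syn
            + i_ext_pn
        )
        v_inf = i_rev / g_tot
        v_pn_new = v_inf + (v_pn - v_inf) * np.exp(-dt * g_tot / cm_pn)

        g_ca_eff = ln.g_ca * ca_m**2 * ca_h
        g_kca_eff = ln.g_kca * kca_m
        g_k_ln = ln.g_k * k_n_ln**4
        g_tot_ln = ln.g_l + ln.g_kl + g_ca_eff + g_kca_eff + g_k_ln + g_gaba_ln + g_ach_ln
        i_rev_ln = (
            ln.g_l * ln.e_l
            + ln.g_kl * ln.e_kl
            + g_ca_eff * ln.e_ca
            + g_kca_eff * ln.e_kca
            + g_k_ln * ln.e_k
            + g_gaba_ln * gaba.e_syn
            + g_ach_ln * nach.e_syn
            + i_ext_ln
        )
        v_inf_ln = i_rev_ln / g_tot_ln
        v_ln_new = v_inf_ln + (v_ln - v_inf_ln) * np.exp(-dt * g_tot_ln / cm_ln)

        # --- spike detection: upward threshold crossing outside refractory
        crossed_pn = (
            (v_pn < c.pn_spike_threshold)
            & (v_pn_new >= c.pn_spike_threshold)
            & (t - last_pn_spike > c.pn_refractory_ms)
        )
        if crossed_pn.any():
            idx = np.nonzero(crossed_pn)[0]
            last_pn_spike[idx] = t
            pn_ids.append(idx)
            pn_ts.append(np.full(len(idx), t + dt))
        crossed_ln = (
            (v_ln < c.ln_spike_threshold)
            & (v_ln_new >= c.ln_spike_threshold)
            & (t - last_ln_spike > c.ln_refractory_ms)
        )
        if crossed_ln.any():
            idx = np.nonzero(crossed_ln)[0]
            last_ln_spike[idx] = t
            ln_ids.append(idx)
            ln_ts.append(np.full(len(idx), t + dt))

        v_pn, v_ln = v_pn_new, v_ln_new
        lfp[n] = v_pn.mean()
        if store_v and n % v_stride == 0:
            rec_pn[n // v_stride] = v_pn
            rec_ln[n // v_stride] = v_ln

        if n % 500 == 0 and (abs(lfp[n]) > 200.0 or not np.isfinite(lfp[n])):
            raise NumericalDivergenceError(
                f"membrane potential diverged at t = {t:.2f} ms (LFP {lfp[n]:.1f} mV)"
            )

    def _table(ids, ts, pop, size):
        if ids:
            return SpikeTable(
                np.concatenate(ids), np.concatenate(ts), pop, size, duration
            )
        return SpikeTable(np.array([], dtype=int), np.array([]), pop, size, duration)

    return ALTrajectory(
        dt=dt,
        duration=duration,
        lfp=lfp,
        pn_spikes=_table(pn_ids, pn_ts, "PN", c.n_pn),
        ln_spikes=_table(ln_ids, ln_ts, "LN", c.n_ln),
        v_pn=rec_pn if store_v else None,
        v_ln=rec_ln if store_v else None,
        v_stride=v_stride,
    )
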