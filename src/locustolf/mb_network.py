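"""Map-based mushroom body: Kenyon cells and output neurons.

Both KCs and MBONs are two-dimensional (Rulkov-style) map neurons in the
regular-spiking regime: a fast variable x with a piecewise nonlinearity
and a slow variable y that sets excitability.  One map iteration
corresponds to ``ms_per_iter`` milliseconds of antennal-lobe time (0.5 ms
by default, so a 50 ms LFP cycle spans 100 iterations).  Synaptic input is
an exponentially decaying current incremented at presynaptic spike
arrivals; neither layer has lateral connections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from locustolf.al_network import SpikeTable

__all__ = [
    "MapNeuronParams",
    "MapSynapseParams",
    "MBConnectivity",
    "map_step",
    "synapse_step",
    "rest_state",
    "build_mb_connectivity",
    "run_kc_layer",
    "run_mbon_layer",
]


@dataclass(frozen=True)
class MapNeuronParams:
    """Two-dimensional map neuron in the regular-spiking regime.

    alpha sets the shape of the fast nonlinearity (3.65: stable rest with
    spiking under drive), mu the slow-variable rate, sigma_dc the constant
    bias (negative: silent without synaptic input).  Synaptic input enters
    both equations: directly in the fast variable and scaled by sigma_e in
    the slow nullcline, so sustained drive produces sustained (not fully
    adapting) spiking.
    """

    alpha: float = 3.65
    mu: float = 0.0005
    sigma_dc: float = -2.0
    sigma_e: float = 1.0
    ms_per_iter: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.mu <= 0 or self.ms_per_iter <= 0:
            raise ValueError("alpha, mu and ms_per_iter must be > 0")


@dataclass(frozen=True)
class MapSynapseParams:
    """Exponential synaptic current onto a map neuron.

    Each presynaptic spike adds ``g_syn * (x_rp - x_post)`` to the
    synaptic current, which otherwise decays by ``gamma`` per iteration.
    With ``x_rp`` above the subthreshold range of x the increment is
    depolarising, i.e. the synapse is excitatory.  The driving force is
    saturated to [0, drive_max]: it vanishes while the orbit is above
    ``x_rp`` (the brief spike plateau) and cannot grow without bound
    after strong inhibitory swings, which would otherwise let dense
    volleys drive a diverging current-orbit feedback loop.
    """

    gamma: float = 0.6
    g_syn: float = 1.0
    x_rp: float = 0.0
    drive_max: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")
        if self.drive_max <= 0.0:
            raise ValueError("drive_max must be > 0")


def map_step(x, x_prev, y, u, alpha: float):
    """One iteration of the fast map variable.

    Piecewise: ``alpha/(1-x) + u`` while subthreshold (x <= 0), a plateau
    at ``alpha + u`` on the upstroke, and a reset to -1 once the orbit has
    peaked (x >= alpha + u, or the previous iterate was suprathreshold).
    """
    x = np.asarray(x, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    u = np.asarray(u, dtype=float)
    sub = x <= 0.0
    rising = (~sub) & (x < alpha + u) & (x_prev <= 0.0)
    with np.errstate(divide="ignore"):
        branch1 = alpha / (1.0 - x) + u
    out = np.where(sub, branch1, np.where(rising, alpha + u, -1.0))
    return out if out.ndim else float(out)


def synapse_step(i_syn, pre_spiked, x_post, params: MapSynapseParams):
    """One iteration of the synaptic current.

    ``pre_spiked`` may be boolean or a spike count (several presynaptic
    spikes in one iteration sum linearly).
    """
    force = np.clip(
        params.x_rp - np.asarray(x_post, dtype=float), 0.0, params.drive_max
    )
    inc = np.asarray(pre_spiked, dtype=float) * params.g_syn * force
    out = params.gamma * np.asarray(i_syn, dtype=float) + inc
    return out if out.ndim else float(out)


def rest_state(params: MapNeuronParams) -> tuple[float, float]:
    """Fixed point (x*, y*) of the coupled map with no synaptic input.

    The slow variable equilibrates where x = sigma_dc - 1; y* then places
    the fast map's stable fixed point there.
    """
    x_star = params.sigma_dc - 1.0
    y_star = x_star - params.alpha / (1.0 - x_star)
    return x_star, y_star


@dataclass(frozen=True)
class MBConnectivity:
    """PN->KC adjacency, KC->MBON weights with mask, and bounds."""

    pn_kc: np.ndarray  # bool, (n_kc, n_pn)
    kc_mbon_mask: np.ndarray  # bool, (n_mbon, n_kc)
    weights: np.ndarray  # float, (n_mbon, n_kc); zero off-mask
    w_min: float
    w_max: float
    seed: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != self.kc_mbon_mask.shape:
            raise ValueError("weights and mask shapes differ")
        on = w[self.kc_mbon_mask]
        if len(on) and (on.min() < self.w_min - 1e-12 or on.max() > self.w_max + 1e-12):
            raise ValueError("weights outside [w_min, w_max]")

    @property
    def n_pn(self) -> int:
        return self.pn_kc.shape[1]

    @property
    def n_kc(self) -> int:
        return self.pn_kc.shape[0]

    @property
    def n_mbon(self) -> int:
        return self.kc_mbon_mask.shape[0]

    def with_weights(self, weights: np.ndarray) -> "MBConnectivity":
        return MBConnectivity(
            pn_kc=self.pn_kc,
            kc_mbon_mask=self.kc_mbon_mask,
            weights=np.where(self.kc_mbon_mask, weights, 0.0),
            w_min=self.w_min,
            w_max=self.w_max,
            seed=self.seed,
        )


def build_mb_connectivity(
    n_pn: int,
    n_kc: int,
    n_mbon: int,
    seed: int,
    p_pn_kc: float = 0.1,
    mbon_kc_frac: float = 0.60,
    w_init: float = 1.0,
    w_min: float = 0.0,
    w_max: float = 2.0,
    w_init_jitter: float = 0.0,
) -> MBConnectivity:
    """Sample mushroom-body connectivity reproducibly from ``seed``.

    Each KC samples each PN independently with ``p_pn_kc``; each MBON
    receives input from a randomly selected ``mbon_kc_frac`` of the KCs.
    Initial weights are ``w_init`` (optionally jittered uniformly by
    ``+-w_init_jitter``) on the mask, clipped to bounds.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pn_kc = rng.random((n_kc, n_pn)) < p_pn_kc
    n_sel = int(round(mbon_kc_frac * n_kc))
    mask = np.zeros((n_mbon, n_kc), dtype=bool)
    for i in range(n_mbon):
        mask[i, rng.choice(n_kc, size=n_sel, replace=False)] = True
    w = np.full((n_mbon, n_kc), float(w_init))
    if w_init_jitter:
        w += rng.uniform(-w_init_jitter, w_init_jitter, size=w.shape)
    w = np.clip(w, w_min, w_max)
    w[~mask] = 0.0
    return MBConnectivity(
        pn_kc=pn_kc, kc_mbon_mask=mask, weights=w, w_min=w_min, w_max=w_max, seed=seed
    )


def _bin_spikes(spikes: SpikeTable, n_iter: int, ms_per_iter: float) -> dict[int, np.ndarray]:
    """Iteration index -> presynaptic neuron ids spiking in that iteration."""
    if len(spikes) == 0:
        return {}
    it = np.floor(spikes.times / ms_per_iter).astype(int)
    valid = (it >= 0) & (it < n_iter)
    it, ids = it[valid], spikes.neuron_ids[valid]
    order = np.argsort(it, kind="stable")
    it, ids = it[order], ids[order]
    out: dict[int, np.ndarray] = {}
    uniq = np.unique(it)
    for u in uniq:
        out[int(u)] = ids[np.searchsorted(it, u) : np.searchsorted(it, u, side="right")]
    return out


def _run_map_layer(
    input_spikes: SpikeTable,
    weight_matrix: np.ndarray,
    neuron: MapNeuronParams,
    syn: MapSynapseParams,
    duration: float,
    population: str,
    on_post_spikes=None,
    on_pre_spikes=None,
    on_iteration=None,
) -> SpikeTable:
    """Drive a layer of map neurons with weighted spike input.

    ``weight_matrix`` is (n_post, n_pre); a presynaptic spike of neuron j
    at iteration n increments every target's synaptic current by
    ``-g_syn * (x_post - x_rp) * w[:, j]``.  Optional callbacks support
    online plasticity.  A spike is an upward zero crossing of x.
    """
    n_post, n_pre = weight_matrix.shape
    if len(input_spikes) and input_spikes.n_neurons != n_pre:
        raise ValueError(
            f"input population size {input_spikes.n_neurons} != weight columns {n_pre}"
        )
    if len(input_spikes) and input_spikes.neuron_ids.max() >= n_pre:
        raise ValueError("spike references unknown presynaptic neuron")
    n_iter = int(np.ceil(duration / neuron.ms_per_iter))
    per_iter = _bin_spikes(input_spikes, n_iter, neuron.ms_per_iter)

    x_star, y_star = rest_state(neuron)
    x = np.full(n_post, x_star)
    x_prev = np.full(n_post, x_star)
    y = np.full(n_post, y_star)
    i_syn = np.zeros(n_post)
    out_ids: list[np.ndarray] = []
    out_ts: list[np.ndarray] = []
    for n in range(n_iter):
        pre = per_iter.get(n)
        i_syn *= syn.gamma
        if pre is not None:
            if on_pre_spikes is not None:
                on_pre_spikes(pre)
            drive = weight_matrix[:, pre].sum(axis=1)
            force = np.clip(syn.x_rp - x, 0.0, syn.drive_max)
            i_syn += syn.g_syn * force * drive
        u = y + i_syn
        x_new = map_step(x, x_prev, y, u, neuron.alpha)
        y = y - neuron.mu * (x + 1.0) + neuron.mu * (
            neuron.sigma_dc + neuron.sigma_e * i_syn
        )
        spiked = (x <= 0.0) & (x_new > 0.0)
        if spiked.any():
            idx = np.nonzero(spiked)[0]
            out_ids.append(idx)
            out_ts.append(np.full(len(idx), (n + 1) * neuron.ms_per_iter))
            if on_post_spikes is not None:
                on_post_spikes(idx)
        if on_iteration is not None:
            on_iteration(n)
        x_prev, x = x, x_new
    if out_ids:
        ids, ts = np.concatenate(out_ids), np.concatenate(out_ts)
    else:
        ids, ts = np.array([], dtype=int), np.array([])
    return SpikeTable(ids, np.minimum(ts, duration), population, n_post, duration)


# calibrated defaults: KC drive such that KC responses stay sparse at
# mid-range integration windows, MBON drive such that a handful of
# coincident KC spikes can fire an MBON
KC_SYNAPSE = MapSynapseParams(gamma=0.9, g_syn=0.3, x_rp=2.0)
MBON_SYNAPSE = MapSynapseParams(gamma=0.9, g_syn=12.0, x_rp=2.0)


def run_kc_layer(
    gated_pn_spikes: SpikeTable,
    connectivity: MBConnectivity,
    params: MapNeuronParams = MapNeuronParams(),
    duration: float | None = None,
    synapse: MapSynapseParams = KC_SYNAPSE,
) -> SpikeTable:
    """Kenyon-cell responses to (phase-gated) PN spikes."""
    if duration is None:
        duration = gated_pn_spikes.duration
    # PN->KC synapses share one strength; weights are normalised by the
    # mean fan-in, so a KC's aggregate input is the fraction of its PNs
    # spiking and g_syn is comparable across network scales.  Selectivity
    # comes from the tail of the (binomial) fan-in overlap distribution:
    # only KCs whose sampled PN subset overlaps the active ensemble more
    # than average reach their high threshold.
    fan_in = max(connectivity.pn_kc.sum(axis=1).mean(), 1.0)
    w = connectivity.pn_kc * (1.0 / fan_in)
    return _run_map_layer(
        gated_pn_spikes, w, params, synapse, duration, population="KC"
    )


def run_mbon_layer(
    kc_spikes: SpikeTable,
    connectivity: MBConnectivity,
    params: MapNeuronParams = MapNeuronParams(),
    duration: float | None = None,
    synapse: MapSynapseParams = MBON_SYNAPSE,
    weight_scale: float = 1.0,
) -> SpikeTable:
    """MBON responses to Kenyon-cell spikes through the plastic weights."""
    if duration is None:
        duration = kc_spikes.duration
    if len(kc_spikes) and kc_spikes.n_neurons != connectivity.n_kc:
        raise ValueError("KC population size does not match weight matrix")
    # weights are normalised by the connected-KC count, so g_syn measures
    # the drive delivered by the whole connected population at w = 1 and
    # the calibration carries across KC-layer sizes
    n_conn = max(connectivity.kc_mbon_mask.sum(axis=1).mean(), 1.0)
    w = connectivity.weights * (weight_scale / n_conn)
    return _run_map_layer(kc_spikes, w, params, synapse, duration, population="MBON")
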