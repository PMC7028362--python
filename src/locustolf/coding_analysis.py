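"""Odor-separation analysis of MBON output.

MBON spike trains are binarised per LFP cycle into MBON x cycle 0/1
matrices; the Hamming distance between two such patterns (identical to
the squared Euclidean distance on binary vectors) measures odor
separation.  Sweeping the gating phase phi traces out distance-vs-phi
curves whose argmax phi* is the optimal integration window; MDS plus a
linear discriminant gives a trial-level classification read-out, and a
paired t-test compares distances before and after STDP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.manifold import MDS

from locustolf.al_network import SpikeTable
from locustolf.lfp_gating import PhaseSeries, gate_spikes
from locustolf.mb_network import (
    MBConnectivity,
    MapNeuronParams,
    MapSynapseParams,
    KC_SYNAPSE,
    MBON_SYNAPSE,
    run_kc_layer,
    run_mbon_layer,
)

__all__ = [
    "BinaryPattern",
    "DistanceCurve",
    "SparsenessMeasure",
    "binarize",
    "pattern_distance",
    "kc_sparseness",
    "mbon_patterns_at_phi",
    "distance_vs_phi",
    "embed_and_classify",
    "paired_comparison",
]


@dataclass(frozen=True)
class BinaryPattern:
    """MBON x LFP-cycle 0/1 response matrix for one trial."""

    matrix: np.ndarray  # (n_mbon, n_cycles) of 0/1
    cycle_bounds: np.ndarray
    label: str = ""
    trial_id: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("pattern entries must be 0 or 1")

    @property
    def n_mbon(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.matrix.shape[1]


@dataclass
class DistanceCurve:
    """Trial-averaged inter-odor distance as a function of phi."""

    phi_grid: np.ndarray
    distances: np.ndarray
    sigma: float | None = None
    snapshot_time: float | None = None

    @property
    def phi_star(self) -> float:
        return float(self.phi_grid[int(np.argmax(self.distances))])

    @property
    def peak_distance(self) -> float:
        return float(np.max(self.distances))


@dataclass(frozen=True)
class SparsenessMeasure:
    """Lifetime sparseness of the KC response to one odor presentation."""

    total_spikes: int
    n_active_kcs: int
    n_kc: int


def kc_sparseness(kc_spikes: SpikeTable) -> SparsenessMeasure:
    return SparsenessMeasure(
        total_spikes=len(kc_spikes),
        n_active_kcs=len(np.unique(kc_spikes.neuron_ids)),
        n_kc=kc_spikes.n_neurons,
    )


def binarize(mbon_spikes: SpikeTable, cycles: PhaseSeries, label: str = "", trial_id: int = 0) -> BinaryPattern:
    """1 iff the MBON spiked at least once within the LFP cycle."""
    bounds = np.asarray(cycles.cycle_bounds, dtype=float)
    if len(bounds) < 2:
        raise ValueError("need at least one complete LFP cycle")
    n_cycles = len(bounds) - 1
    mat = np.zeros((mbon_spikes.n_neurons, n_cycles), dtype=np.int8)
    if len(mbon_spikes):
        cyc = np.searchsorted(bounds, mbon_spikes.times, side="right") - 1
        ok = (cyc >= 0) & (cyc < n_cycles)
        mat[mbon_spikes.neuron_ids[ok], cyc[ok]] = 1
    return BinaryPattern(matrix=mat, cycle_bounds=bounds, label=label, trial_id=trial_id)


def pattern_distance(p1: BinaryPattern, p2: BinaryPattern, normalized: bool = False) -> float:
    """Hamming distance between two binary spatiotemporal patterns.

    Equal to the squared Euclidean distance between the 0/1 vectors.  The
    cycle count can differ by a little between trials (noise moves trough
    positions); both patterns are truncated to the shared cycle range.
    """
    if p1.n_mbon != p2.n_mbon:
        raise ValueError("patterns have different MBON counts")
    n = min(p1.n_cycles, p2.n_cycles)
    a = p1.matrix[:, :n]
    b = p2.matrix[:, :n]
    d = float(np.count_nonzero(a != b))
    return d / (p1.n_mbon * n) if normalized else d


def mbon_patterns_at_phi(
    trials,
    connectivity: MBConnectivity,
    phi: float,
    neuron: MapNeuronParams = MapNeuronParams(),
    kc_synapse: MapSynapseParams = KC_SYNAPSE,
    mbon_synapse: MapSynapseParams = MBON_SYNAPSE,
    weight_scale: float = 1.0,
):
    """Run gate -> KC -> MBON -> binarize for a set of prepared AL trials.

    ``trials`` is a sequence of objects with ``pn_spikes`` (SpikeTable),
    ``phase`` (PhaseSeries) and ``label`` attributes, one per AL trial.
    Returns (patterns, kc_tables).
    """
    patterns, kc_tables = [], []
    for k, tr in enumerate(trials):
        gated = gate_spikes(tr.pn_spikes, tr.phase, phi)
        kc = run_kc_layer(gated, connectivity, params=neuron, synapse=kc_synapse)
        mbon = run_mbon_layer(
            kc, connectivity, params=neuron, synapse=mbon_synapse, weight_scale=weight_scale
        )
        patterns.append(binarize(mbon, tr.phase, label=tr.label, trial_id=k))
        kc_tables.append(kc)
    return patterns, kc_tables


def distance_vs_phi(
    trials_a,
    trials_b,
    connectivity: MBConnectivity,
    phi_grid,
    neuron: MapNeuronParams = MapNeuronParams(),
    kc_synapse: MapSynapseParams = KC_SYNAPSE,
    mbon_synapse: MapSynapseParams = MBON_SYNAPSE,
    weight_scale: float = 1.0,
    sigma: float | None = None,
    snapshot_time: float | None = None,
) -> DistanceCurve:
    """Trial-averaged inter-odor Hamming distance at each gating phase.

    For each phi the full downstream pipeline (gate at phi -> KC -> MBON ->
    binary pattern) runs on every prepared AL trial of both odors; the
    reported distance is the mean over all cross-odor trial pairs.
    """
    phi_grid = np.asarray(phi_grid, dtype=float)
    dists = np.empty(len(phi_grid))
    for i, phi in enumerate(phi_grid):
        pats_a, _ = mbon_patterns_at_phi(
            trials_a, connectivity, phi, neuron, kc_synapse, mbon_synapse, weight_scale
        )
        pats_b, _ = mbon_patterns_at_phi(
            trials_b, connectivity, phi, neuron, kc_synapse, mbon_synapse, weight_scale
        )
        pair_d = [pattern_distance(pa, pb) for pa in pats_a for pb in pats_b]
        dists[i] = float(np.mean(pair_d))
    return DistanceCurve(
        phi_grid=phi_grid, distances=dists, sigma=sigma, snapshot_time=snapshot_time
    )


def distance_matrix(patterns) -> np.ndarray:
    """Symmetric pairwise Hamming distance matrix over trials."""
    n = len(patterns)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = pattern_distance(patterns[i], patterns[j])
    return d


def embed_and_classify(
    dist_matrix: np.ndarray, labels, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Metric MDS to 2D preserving Hamming distances, then a linear
    discriminant on the plane; returns (coordinates, misclassified count).
    """
    d = np.asarray(dist_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if np.allclose(d, 0.0):
        raise ValueError("degenerate all-zero distance matrix")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    try:
        mds = MDS(
            n_components=2,
            metric="precomputed",
            init="random",
            random_state=seed,
            normalized_stress=False,
        )
        coords = mds.fit_transform(d)
    except (TypeError, ValueError):  # older sklearn API
        mds = MDS(
            n_components=2,
            dissimilarity="precomputed",
            random_state=seed,
            normalized_stress=False,
        )
        coords = mds.fit_transform(d)
    if len(labels) <= len(np.unique(labels)):
        # one point per class: trivially separable, nothing to fit
        return coords, 0
    lda = LinearDiscriminantAnalysis()
    lda.fit(coords, labels)
    mis = int(np.sum(lda.predict(coords) != labels))
    return coords, mis


def paired_comparison(pre_distances, post_distances) -> tuple[float, float, float]:
    """Two-sided paired t-test of post-STDP vs pre-STDP odor distances.

    Returns (mean difference post - pre, t statistic, p value).
    """
    pre = np.asarray(pre_distances, dtype=float)
    post = np.asarray(post_distances, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if len(pre) < 2:
        raise ValueError("need at least two pairs")
    diff = post - pre
    if np.ptp(diff) < 1e-300 and np.std(diff) == 0.0:
        if np.allclose(diff, 0.0):
            return 0.0, 0.0, 1.0
        raise ValueError("zero-variance differences: t statistic undefined")
    t, p = stats.ttest_rel(post, pre)
    return float(diff.mean()), float(t), float(p)
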