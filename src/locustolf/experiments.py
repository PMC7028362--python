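"""End-to-end experiment orchestration.

Three seeded, fully reproducible experiments mirror the package's core
analyses: an antennal-lobe demonstration (rasters, LFP and its spectrum),
a phi x sigma sweep of inter-odor distance with a uniform-weight variant,
and the STDP experiment (weight evolution from two initialisations,
pre/post distance curves, paired test, MDS + linear-discriminant
classification).  Every artifact is derived from an ExperimentConfig plus
a master seed; child seeds are spawned deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from locustolf.al_network import (
    ALConfig,
    ALTrajectory,
    build_al_network,
    integrate_al,
)
from locustolf.coding_analysis import (
    DistanceCurve,
    distance_matrix,
    distance_vs_phi,
    embed_and_classify,
    kc_sparseness,
    mbon_patterns_at_phi,
    paired_comparison,
)
from locustolf.lfp_gating import compute_lfp, dominant_frequency, filter_and_phase
from locustolf.mb_network import (
    KC_SYNAPSE,
    MBON_SYNAPSE,
    MapNeuronParams,
    build_mb_connectivity,
)
from locustolf.plasticity import STDPParams, train
from locustolf.lfp_gating import gate_spikes
from locustolf.mb_network import run_kc_layer
from locustolf.stimulus import OdorSpec, StimulusProtocol, make_trial

__all__ = [
    "ExperimentConfig",
    "PreparedTrial",
    "prepare_trial",
    "two_cell_pair_frequency",
    "run_al_demo",
    "run_phi_sweep",
    "run_stdp_experiment",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Scale preset and experiment schedule.

    ``reference`` is the full-size system (350 PN / 100 LN / 15,000 KC /
    100 MBON); ``ci`` is a scaled-down preset for desk-scale runs.
    """

    scale: str = "ci"
    n_pn: int = 100
    n_ln: int = 30
    n_kc: int = 1500
    n_mbon: int = 20
    odor_peak_frac: float = 0.5  # peak position as a fraction of n_pn
    peak_shift_similar: float = 5.0
    peak_shift_distinct: float = 20.0
    sigmas: tuple[float, ...] = (0.2, 0.25, 0.35)
    amplitude: float = 7.0
    phi_grid: tuple[float, ...] = tuple(np.round(np.linspace(np.pi / 4, 2 * np.pi, 8), 4))
    n_trials: int = 2
    n_train_presentations: int = 60
    rise_ms: float = 60.0
    plateau_ms: float = 1000.0
    decay_ms: float = 200.0
    noise_frac: float = 0.075
    train_phi: float = np.pi
    stdp: STDPParams = STDPParams()

    @classmethod
    def preset(cls, scale: str, **overrides) -> "ExperimentConfig":
        if scale == "reference":
            base = dict(
                scale="reference", n_pn=350, n_ln=100, n_kc=15000, n_mbon=100,
                n_trials=5,
            )
        elif scale == "ci":
            base = dict(scale="ci", n_pn=100, n_ln=30, n_kc=1500, n_mbon=20,
                        plateau_ms=600.0)
        else:
            raise ValueError("scale must be 'reference' or 'ci'")
        base.update(overrides)
        return cls(**base)

    def al_config(self) -> ALConfig:
        n_exc = max(1, int(round(self.n_pn * 50 / 350)))
        return ALConfig(n_pn=self.n_pn, n_ln=self.n_ln, n_exc_pn=n_exc)

    def protocol(self) -> StimulusProtocol:
        return StimulusProtocol(
            rise_ms=self.rise_ms,
            plateau_ms=self.plateau_ms,
            decay_ms=self.decay_ms,
            noise_frac=self.noise_frac,
        )

    def odor(self, sigma: float, shift: float = 0.0, label: str | None = None) -> OdorSpec:
        return OdorSpec(
            peak_index=self.odor_peak_frac * self.n_pn + shift,
            sigma=sigma,
            amplitude=self.amplitude,
            label=label if label is not None else f"odor(shift={shift:g},sigma={sigma:g})",
        )

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o).__name__)

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)


@dataclass
class PreparedTrial:
    """An AL trial ready for the downstream pipeline."""

    pn_spikes: "SpikeTable"
    phase: "PhaseSeries"
    lfp: "LFPTrace"
    label: str
    seed: int
    trajectory: ALTrajectory | None = None


def prepare_trial(network, odor, cfg: ExperimentConfig, seed: int,
                  trial_index: int = 0, keep_trajectory: bool = False) -> PreparedTrial:
    """Simulate one AL trial and extract LFP phase for gating."""
    stim = make_trial(
        odor, cfg.n_pn, cfg.n_ln, protocol=cfg.protocol(),
        trial_index=trial_index, seed=seed,
    )
    traj = integrate_al(network, stim)
    lfp = compute_lfp(traj)
    phase = filter_and_phase(
        lfp, window=(cfg.rise_ms + 150.0, cfg.rise_ms + cfg.plateau_ms)
    )
    return PreparedTrial(
        pn_spikes=traj.pn_spikes,
        phase=phase,
        lfp=lfp,
        label=odor.label,
        seed=seed,
        trajectory=traj if keep_trajectory else None,
    )


def _child_seeds(master_seed: int, n: int, salt: int = 0) -> list[int]:
    ss = np.random.SeedSequence([master_seed, salt])
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _manifest(out_dir: Path, name: str, cfg: ExperimentConfig, seed: int, t0: float, extra: dict):
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "experiment": name,
        "seed": seed,
        "scale": cfg.scale,
        "elapsed_s": round(time.time() - t0, 2),
        **extra,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "config.json").write_text(cfg.to_json())
    return manifest


def burst_onsets(times: np.ndarray, gap_ms: float = 15.0) -> np.ndarray:
    """Group spikes into bursts split at inter-spike gaps > ``gap_ms``."""
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        return times
    starts = np.concatenate([[True], np.diff(times) > gap_ms])
    return times[starts]


def two_cell_pair_frequency(
    g_gaba: float = 1.0,
    g_nach: float = 0.3,
    i_pn: float = 9.0,
    i_ln: float = 6.0,
    duration: float = 2000.0,
    dt: float = 0.02,
) -> dict:
    """Oscillation of one PN reciprocally coupled to one LN under DC drive.

    The PN excites the LN through the nicotinic synapse; the LN inhibits
    the PN through the fast GABAergic synapse.  Constant suprathreshold
    drive (no noise) produces antiphase bursting; the reported frequency is
    1000 / (mean PN inter-burst interval in ms).
    """
    from locustolf.stimulus import StimulusProtocol, StimulusTrial

    cfg = ALConfig(
        n_pn=1, n_ln=1, n_exc_pn=0,
        p_pn_ln=1.0, p_ln_pn=1.0, p_ln_ln=0.0, p_pn_pn=0.0,
        g_pn_ln=g_nach, g_ln_pn=g_gaba,
    )
    net = build_al_network(cfg, seed=0)
    proto = StimulusProtocol(rise_ms=10.0, plateau_ms=duration, decay_ms=50.0,
                             noise_frac=1e-9)
    odor = OdorSpec(peak_index=0, sigma=10.0, amplitude=max(i_pn, i_ln),
                    threshold_frac=0.0)
    stim = StimulusTrial(
        odor=odor,
        pn_amplitudes=np.array([i_pn]),
        ln_amplitudes=np.array([i_ln]),
        protocol=proto,
        seed=0,
    )
    traj = integrate_al(net, stim, duration=duration, dt=dt, seed=0)
    onsets = burst_onsets(traj.pn_spikes.times)
    if len(onsets) < 4:
        raise RuntimeError("pair did not oscillate: fewer than four PN bursts")
    ibis = np.diff(onsets)[1:]  # drop the onset transient
    period = float(np.mean(ibis))
    return {
        "period_ms": period,
        "frequency_hz": 1000.0 / period,
        "n_bursts": int(len(onsets)),
        "n_pn_spikes": len(traj.pn_spikes),
        "n_ln_spikes": len(traj.ln_spikes),
    }


def run_al_demo(cfg: ExperimentConfig, seed: int, out_dir: str | Path,
                sigma: float = 0.25, gaba_blocked: bool = False) -> dict:
    """Antennal-lobe demonstration: rasters, LFP trace and spectrum."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    al_cfg = cfg.al_config()
    if gaba_blocked:
        al_cfg = dataclasses.replace(al_cfg, g_ln_pn=0.0, g_ln_ln=0.0)
    net = build_al_network(al_cfg, seed=_child_seeds(seed, 1, salt=1)[0])
    trial = prepare_trial(net, cfg.odor(sigma), cfg, _child_seeds(seed, 1, salt=2)[0])
    peak_hz, freqs, power = dominant_frequency(
        trial.lfp, window=(cfg.rise_ms + 200.0, cfg.rise_ms + cfg.plateau_ms)
    )
    trial.pn_spikes.to_csv(out / "pn_spikes.csv")
    np.savetxt(
        out / "lfp.csv",
        np.column_stack([trial.lfp.times, trial.lfp.samples]),
        delimiter=",", header="t_ms,lfp_mV", comments="",
    )
    band = (freqs >= 1) & (freqs <= 60)
    np.savetxt(
        out / "lfp_spectrum.csv",
        np.column_stack([freqs[band], power[band]]),
        delimiter=",", header="freq_hz,power", comments="",
    )
    extra = {
        "lfp_peak_hz": peak_hz,
        "n_pn_spikes": len(trial.pn_spikes),
        "gaba_blocked": gaba_blocked,
    }
    return _manifest(out, "al_demo", cfg, seed, t0, extra)


def run_phi_sweep(cfg: ExperimentConfig, seed: int, out_dir: str | Path,
                  weight_scales: tuple[float, ...] = (0.1, 0.5, 0.9)) -> dict:
    """Distance-vs-phi curves per sigma, KC sparseness, and the
    uniform-weight variant reporting phi* per KC->MBON weight scale."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = build_al_network(cfg.al_config(), seed=_child_seeds(seed, 1, salt=1)[0])
    conn = build_mb_connectivity(
        cfg.n_pn, cfg.n_kc, cfg.n_mbon, seed=_child_seeds(seed, 1, salt=3)[0]
    )
    phi_grid = np.asarray(cfg.phi_grid)
    results = {"sigma_curves": {}, "kc_counts": {}, "weight_variant": {}}
    for sigma in cfg.sigmas:
        odor_a = cfg.odor(sigma, 0.0, label="A")
        odor_b = cfg.odor(sigma, cfg.peak_shift_similar, label="B")
        seeds = _child_seeds(seed, 2 * cfg.n_trials, salt=int(sigma * 1000))
        trials_a = [
            prepare_trial(net, odor_a, cfg, s, trial_index=i)
            for i, s in enumerate(seeds[: cfg.n_trials])
        ]
        trials_b = [
            prepare_trial(net, odor_b, cfg, s, trial_index=i)
            for i, s in enumerate(seeds[cfg.n_trials :])
        ]
        curve = distance_vs_phi(trials_a, trials_b, conn, phi_grid, sigma=sigma)
        results["sigma_curves"][str(sigma)] = {
            "phi": phi_grid.tolist(),
            "distance": curve.distances.tolist(),
            "phi_star": curve.phi_star,
        }
        counts = []
        for phi in phi_grid:
            gated = gate_spikes(trials_a[0].pn_spikes, trials_a[0].phase, phi)
            kc = run_kc_layer(gated, conn)
            counts.append(kc_sparseness(kc).total_spikes)
        results["kc_counts"][str(sigma)] = counts
        if sigma == max(cfg.sigmas):
            for ws in weight_scales:
                c = distance_vs_phi(
                    trials_a, trials_b, conn, phi_grid, weight_scale=ws, sigma=sigma
                )
                results["weight_variant"][str(ws)] = {
                    "distance": c.distances.tolist(),
                    "phi_star": c.phi_star,
                }
    (out / "phi_sweep.json").write_text(json.dumps(results, indent=2))
    return _manifest(out, "phi_sweep", cfg, seed, t0, {"results": "phi_sweep.json"})


def run_stdp_experiment(cfg: ExperimentConfig, seed: int, out_dir: str | Path,
                        init_weights: tuple[float, ...] = (1.4, 0.6)) -> dict:
    """STDP experiment: weight evolution, pre/post distance curves at the
    snapshot weights, phi* invariance check, paired test and MDS + LDA."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = build_al_network(cfg.al_config(), seed=_child_seeds(seed, 1, salt=1)[0])
    phi_grid = np.asarray(cfg.phi_grid)
    sigma_pair = (min(cfg.sigmas), max(cfg.sigmas))

    # AL trial bank: two similar odors and one distinct, per sigma
    bank: dict[tuple[float, str], list[PreparedTrial]] = {}
    for sigma in sigma_pair:
        for name, shift in (("A", 0.0), ("B", cfg.peak_shift_similar),
                            ("C", cfg.peak_shift_distinct)):
            odor = cfg.odor(sigma, shift, label=name)
            seeds = _child_seeds(seed, cfg.n_trials, salt=hash((sigma, name)) % 10000)
            bank[(sigma, name)] = [
                prepare_trial(net, odor, cfg, s, trial_index=i)
                for i, s in enumerate(seeds)
            ]

    # training schedule: interleaved KC responses gated at train_phi
    rng = np.random.default_rng(_child_seeds(seed, 1, salt=7)[0])
    conn0 = build_mb_connectivity(
        cfg.n_pn, cfg.n_kc, cfg.n_mbon, seed=_child_seeds(seed, 1, salt=3)[0]
    )
    train_pool = []
    for sigma in sigma_pair:
        for name in ("A", "B", "C"):
            for tr in bank[(sigma, name)]:
                gated = gate_spikes(tr.pn_spikes, tr.phase, cfg.train_phi)
                train_pool.append(run_kc_layer(gated, conn0))
    sched_idx = rng.integers(0, len(train_pool), size=cfg.n_train_presentations)
    schedule = [train_pool[i] for i in sched_idx]

    report: dict = {"init_weights": {}, "curves": {}, "classification": {}}
    trained = {}
    for w0 in init_weights:
        conn = build_mb_connectivity(
            cfg.n_pn, cfg.n_kc, cfg.n_mbon,
            seed=_child_seeds(seed, 1, salt=3)[0],
            w_init=w0, w_init_jitter=0.05,
        )
        conn_post, hist = train(conn, schedule, stdp=cfg.stdp)
        trained[w0] = (conn, conn_post)
        report["init_weights"][str(w0)] = {
            "times_ms": hist.times,
            "median": hist.median_trajectory.tolist(),
            "n_changed": int(hist.changed_mask.sum()),
        }

    conn_pre, conn_post = trained[init_weights[0]]
    phi_star_by_sigma = {}
    for sigma in sigma_pair:
        a, b = bank[(sigma, "A")], bank[(sigma, "B")]
        c_pre = distance_vs_phi(a, b, conn_pre, phi_grid, sigma=sigma)
        c_post = distance_vs_phi(a, b, conn_post, phi_grid, sigma=sigma)
        phi_star_by_sigma[sigma] = c_pre.phi_star
        report["curves"][str(sigma)] = {
            "phi": phi_grid.tolist(),
            "pre": c_pre.distances.tolist(),
            "post": c_post.distances.tolist(),
            "phi_star_pre": c_pre.phi_star,
            "phi_star_post": c_post.phi_star,
            "peak_pre": c_pre.peak_distance,
            "peak_post": c_post.peak_distance,
        }

    # paired test: per-trial-pair distances at the pre-training phi*, over
    # the three odor pairs at each concentration
    from locustolf.coding_analysis import pattern_distance

    pre_d, post_d = [], []
    for sigma in sigma_pair:
        phi_star = phi_star_by_sigma[sigma]
        pats = {}
        for tag, conn in (("pre", conn_pre), ("post", conn_post)):
            for name in ("A", "B", "C"):
                pats[(tag, name)], _ = mbon_patterns_at_phi(
                    bank[(sigma, name)], conn, phi_star
                )
        for n1, n2 in (("A", "B"), ("A", "C"), ("B", "C")):
            for pa in range(len(pats[("pre", n1)])):
                for pb in range(len(pats[("pre", n2)])):
                    pre_d.append(
                        pattern_distance(pats[("pre", n1)][pa], pats[("pre", n2)][pb])
                    )
                    post_d.append(
                        pattern_distance(pats[("post", n1)][pa], pats[("post", n2)][pb])
                    )
    mean_diff, t_stat, p_val = paired_comparison(pre_d, post_d)
    report["paired_test"] = {
        "mean_diff": mean_diff, "t": t_stat, "p": p_val, "n_pairs": len(pre_d),
    }

    # classification at phi*: MDS + LDA on single-trial patterns
    sigma = sigma_pair[1]
    a, b = bank[(sigma, "A")], bank[(sigma, "B")]
    phi_star = report["curves"][str(sigma)]["phi_star_pre"]
    for tag, conn in (("pre", conn_pre), ("post", conn_post)):
        pats_a, _ = mbon_patterns_at_phi(a, conn, phi_star)
        pats_b, _ = mbon_patterns_at_phi(b, conn, phi_star)
        pats = pats_a + pats_b
        labels = [0] * len(pats_a) + [1] * len(pats_b)
        d = distance_matrix(pats)
        try:
            _, mis = embed_and_classify(d, labels, seed=seed % (2**31))
        except ValueError:
            mis = None
        report["classification"][tag] = mis
    (out / "stdp_report.json").write_text(json.dumps(report, indent=2))
    return _manifest(out, "stdp_run", cfg, seed, t0, {"results": "stdp_report.json"})
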