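"""LFP extraction, instantaneous 20 Hz phase, and phase-gating of PN spikes.

The local field potential is the mean PN membrane potential.  Gating
emulates the feedback inhibition Kenyon cells receive from the giant
GABAergic neuron: within each oscillation cycle (trough to trough of the
filtered LFP), PN spikes whose instantaneous phase exceeds a threshold phi
are removed, so phi directly controls the window of integration and hence
the sparseness of the downstream Kenyon-cell response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from locustolf.al_network import ALTrajectory, SpikeTable

__all__ = [
    "LFPTrace",
    "PhaseSeries",
    "compute_lfp",
    "filter_and_phase",
    "gate_spikes",
    "dominant_frequency",
]


@dataclass(frozen=True)
class LFPTrace:
    """Mean PN membrane potential at the integration resolution."""

    samples: np.ndarray
    dt: float  # ms

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt

    @property
    def fs_hz(self) -> float:
        return 1000.0 / self.dt


@dataclass(frozen=True)
class PhaseSeries:
    """Filtered LFP with instantaneous phase and cycle boundaries.

    ``phase`` is the analytic-signal angle in (-pi, pi]; cycle boundaries
    are the trough times (phase-wrap points) within the analysis window.
    The within-cycle phase of an event, measured from the preceding trough,
    is ``phase + pi`` in [0, 2 pi).
    """

    filtered: np.ndarray
    phase: np.ndarray
    dt: float
    cycle_bounds: np.ndarray  # trough times, ms, strictly increasing
    window: tuple[float, float]  # (start, end) of the analysis window, ms

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.filtered)) * self.dt

    @property
    def n_cycles(self) -> int:
        return max(len(self.cycle_bounds) - 1, 0)

    def cycle_durations(self) -> np.ndarray:
        return np.diff(self.cycle_bounds)

    def phase_at(self, t) -> np.ndarray:
        """Within-cycle phase in [0, 2 pi) at time(s) t; NaN outside cycles."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.clip(np.round(t / self.dt).astype(int), 0, len(self.phase) - 1)
        ph = np.mod(self.phase[idx] + np.pi, 2.0 * np.pi)
        outside = (t < self.cycle_bounds[0]) | (t >= self.cycle_bounds[-1])
        ph[outside] = np.nan
        return ph


def compute_lfp(trajectory: ALTrajectory) -> LFPTrace:
    """LFP = pointwise mean membrane potential over the PN population."""
    if trajectory.lfp is None or len(trajectory.lfp) == 0:
        raise ValueError("trajectory has no PN voltage samples")
    return LFPTrace(samples=np.asarray(trajectory.lfp, dtype=float), dt=trajectory.dt)


def filter_and_phase(
    lfp: LFPTrace,
    cutoff_hz: float = 40.0,
    window: tuple[float, float] | None = None,
    baseline_hz: float = 5.0,
    order: int = 4,
) -> PhaseSeries:
    """Zero-phase low-pass filter, analytic-signal phase and cycle troughs.

    A forward-backward Butterworth low-pass at ``cutoff_hz`` removes fast
    structure; a second low-pass at ``baseline_hz`` estimates the slow
    stimulus-locked baseline, which is subtracted before the Hilbert
    transform so that the phase tracks the oscillation rather than the
    envelope.  Troughs (phase-wrap points of the analytic signal) are
    detected only inside ``window``, by default from 200 ms after the start
    of the trace to its end, skipping the onset transient.
    """
    x = np.asarray(lfp.samples, dtype=float)
    if len(x) < 10:
        raise ValueError("trace too short to filter")
    if np.ptp(x) < 1e-12:
        raise ValueError("no oscillation: flat LFP trace")
    fs = lfp.fs_hz
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    low = signal.sosfiltfilt(sos, x)
    sos_b = signal.butter(order, baseline_hz, btype="low", fs=fs, output="sos")
    osc = low - signal.sosfiltfilt(sos_b, x)

    if window is None:
        window = (200.0, len(x) * lfp.dt)
    i0 = max(int(window[0] / lfp.dt), 0)
    i1 = min(int(window[1] / lfp.dt), len(x))
    if i1 - i0 < 10:
        raise ValueError("analysis window too short")
    phase = np.angle(signal.hilbert(osc))
    # troughs: phase wraps from +pi to -pi
    wrap = np.nonzero(np.diff(phase[i0:i1]) < -np.pi)[0] + i0 + 1
    bounds = wrap * lfp.dt
    return PhaseSeries(
        filtered=osc,
        phase=phase,
        dt=lfp.dt,
        cycle_bounds=bounds,
        window=(i0 * lfp.dt, i1 * lfp.dt),
    )


def gate_spikes(spikes: SpikeTable, phase: PhaseSeries, phi: float) -> SpikeTable:
    """Remove spikes whose within-cycle phase exceeds ``phi``.

    A spike at within-cycle phase theta (measured from the preceding LFP
    trough) survives iff theta <= phi.  Spikes before the first or after
    the last detected trough fall outside the oscillatory epoch and are
    retained unmodified.
    """
    if not 0.0 <= phi <= 2.0 * np.pi + 1e-4:
        raise ValueError("phi must be in [0, 2 pi]")
    phi = min(phi, 2.0 * np.pi)
    if len(spikes) == 0 or len(phase.cycle_bounds) < 2:
        return spikes
    theta = phase.phase_at(spikes.times)
    keep = np.isnan(theta) | (theta <= phi)
    return SpikeTable(
        neuron_ids=spikes.neuron_ids[keep],
        times=spikes.times[keep],
        population=spikes.population,
        n_neurons=spikes.n_neurons,
        duration=spikes.duration,
    )


def dominant_frequency(
    lfp: LFPTrace,
    window: tuple[float, float],
    band: tuple[float, float] = (5.0, 40.0),
    resolution_hz: float = 0.25,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Dominant spectral peak of the LFP inside a time window and band.

    Returns ``(peak_hz, freqs, power)`` from a periodogram of the detrended
    segment, zero-padded to ``resolution_hz`` bin spacing.
    """
    i0, i1 = (max(int(w / lfp.dt), 0) for w in window)
    seg = np.asarray(lfp.samples[i0:i1], dtype=float)
    if len(seg) < 16:
        raise ValueError("window too short for a spectrum")
    seg = signal.detrend(seg)
    fs = lfp.fs_hz
    nfft = max(len(seg), int(fs / resolution_hz))
    freqs, power = signal.periodogram(seg, fs=fs, nfft=nfft, window="hann")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError("band outside spectral range")
    fb, pb = freqs[in_band], power[in_band]
    return float(fb[np.argmax(pb)]), freqs, power
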