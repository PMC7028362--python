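"""Parametric odor stimuli.

An odor is a Gaussian profile of input amplitudes over the (arbitrarily
ordered) neuron index: the peak position encodes odor identity, the width
sigma encodes concentration (a wider Gaussian recruits more neurons, as
higher concentrations do).  The temporal envelope of each presentation is
a 60 ms rise, a 1000 ms plateau carrying 5-10% amplitude noise, and a
200 ms decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OdorSpec",
    "StimulusProtocol",
    "StimulusTrial",
    "amplitude_profile",
    "envelope",
    "make_trial_schedule",
]


@dataclass(frozen=True)
class OdorSpec:
    """Odor identity and concentration in input-amplitude space.

    Parameters
    ----------
    peak_index : float
        Index of the most strongly driven neuron (identity).
    sigma : float
        Gaussian width as a fraction of the index range (concentration).
    amplitude : float
        Peak input current (model units, nA).
    threshold_frac : float
        Fraction of the peak below which the input is set to exactly zero.
    """

    peak_index: float
    sigma: float
    amplitude: float = 1.0
    threshold_frac: float = 0.05
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.threshold_frac < 1:
            raise ValueError("threshold_frac must be in [0, 1)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    def shifted(self, delta: float, label: str | None = None) -> "OdorSpec":
        """A second odor whose peak is shifted by ``delta`` index units."""
        return replace(
            self,
            peak_index=self.peak_index + delta,
            label=label if label is not None else f"{self.label}+{delta:g}",
        )


@dataclass(frozen=True)
class StimulusProtocol:
    """Temporal envelope of one odor presentation (all durations in ms)."""

    rise_ms: float = 60.0
    plateau_ms: float = 1000.0
    decay_ms: float = 200.0
    noise_frac: float = 0.075

    def __post_init__(self) -> None:
        if min(self.rise_ms, self.plateau_ms, self.decay_ms) <= 0:
            raise ValueError("all durations must be > 0")
        if not 0 <= self.noise_frac < 1:
            raise ValueError("noise_frac must be in [0, 1)")

    @property
    def stim_end_ms(self) -> float:
        """End of the constant-amplitude plateau."""
        return self.rise_ms + self.plateau_ms

    def total_ms(self, decay_tails: float = 2.0) -> float:
        """Suggested trial duration: envelope plus ``decay_tails`` e-folds."""
        return self.stim_end_ms + decay_tails * self.decay_ms


def amplitude_profile(odor: OdorSpec, n_neurons: int) -> np.ndarray:
    """Per-neuron input amplitudes for one odor.

    The profile is a Gaussian over a *circular* index space (so shifted
    odors are statistically identical wherever the peak sits), centred at
    ``odor.peak_index`` with width ``odor.sigma * n_neurons``, thresholded
    to exactly zero below ``threshold_frac`` of the peak.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    idx = np.arange(n_neurons, dtype=float)
    d = np.abs(idx - (odor.peak_index % n_neurons))
    d = np.minimum(d, n_neurons - d)  # circular distance
    width = odor.sigma * n_neurons
    prof = odor.amplitude * np.exp(-0.5 * (d / width) ** 2)
    prof[prof < odor.threshold_frac * odor.amplitude] = 0.0
    return prof


def envelope(t, protocol: StimulusProtocol = StimulusProtocol()):
    """Dimensionless stimulus envelope at time(s) ``t`` (ms).

    Half-cosine rise over ``rise_ms``, constant 1 during the plateau,
    exponential decay with time constant ``decay_ms`` afterwards.
    """
    t = np.asarray(t, dtype=float)
    rise, plateau, tau = protocol.rise_ms, protocol.plateau_ms, protocol.decay_ms
    out = np.zeros_like(t)
    rising = (t > 0) & (t < rise)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / rise))
    flat = (t >= rise) & (t <= rise + plateau)
    out[flat] = 1.0
    falling = t > rise + plateau
    out[falling] = np.exp(-(t[falling] - rise - plateau) / tau)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class StimulusTrial:
    """One presentation of one odor: amplitudes, envelope and noise seed."""

    odor: OdorSpec
    pn_amplitudes: np.ndarray
    ln_amplitudes: np.ndarray
    protocol: StimulusProtocol
    trial_index: int = 0
    seed: int = 0

    @property
    def label(self) -> str:
        return self.odor.label

    def envelope(self, t):
        return envelope(t, self.protocol)


def make_trial(
    odor: OdorSpec,
    n_pn: int,
    n_ln: int,
    protocol: StimulusProtocol = StimulusProtocol(),
    trial_index: int = 0,
    seed: int = 0,
    ln_input_ratio: float = 0.6,
) -> StimulusTrial:
    """Build a single :class:`StimulusTrial` for one odor.

    LNs receive the same Gaussian shape over their own index range (peak at
    the same fractional position), scaled by ``ln_input_ratio``.
    """
    pn_amp = amplitude_profile(odor, n_pn)
    ln_odor = replace(
        odor,
        peak_index=odor.peak_index / n_pn * n_ln,
        sigma=odor.sigma,
        amplitude=odor.amplitude * ln_input_ratio,
    )
    ln_amp = amplitude_profile(ln_odor, n_ln)
    return StimulusTrial(
        odor=odor,
        pn_amplitudes=pn_amp,
        ln_amplitudes=ln_amp,
        protocol=protocol,
        trial_index=trial_index,
        seed=seed,
    )


def make_trial_schedule(
    odors: list[OdorSpec],
    n_trials_each: int,
    seed: int,
    n_pn: int,
    n_ln: int,
    protocol: StimulusProtocol = StimulusProtocol(),
    ln_input_ratio: float = 0.6,
) -> list[StimulusTrial]:
    """Randomly interleaved schedule of ``n_trials_each`` trials per odor.

    The order and every per-trial noise seed derive deterministically from
    ``seed``; repeated calls with the same arguments give the same schedule.
    """
    if not odors:
        raise ValueError("odor list must not be empty")
    if n_trials_each < 1:
        raise ValueError("n_trials_each must be >= 1")
    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    slots = np.repeat(np.arange(len(odors)), n_trials_each)
    order_rng.shuffle(slots)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(slots))]
    counters = [0] * len(odors)
    trials = []
    for slot, child in zip(slots, child_seeds):
        odor = odors[slot]
        trials.append(
            make_trial(
                odor,
                n_pn,
                n_ln,
                protocol=protocol,
                trial_index=counters[slot],
                seed=child,
                ln_input_ratio=ln_input_ratio,
            )
        )
        counters[slot] += 1
    return trials
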