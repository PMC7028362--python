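"""Shared fixtures: a desk-scale antennal-lobe trial bank, computed once.

Antennal-lobe simulations dominate the suite's runtime, so every test that
needs network output draws from a session-scoped, lazily filled cache of
prepared trials (spikes + LFP phase) at the CI preset scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from locustolf.al_network import build_al_network
from locustolf.experiments import ExperimentConfig, prepare_trial, _child_seeds
from locustolf.mb_network import build_mb_connectivity

NET_SEED = 101
MB_SEED = 202
TRIAL_SEED = 55

SHIFTS = {"A": 0.0, "B": 5.0, "C": 20.0}


@pytest.fixture(scope="session")
def ci_config() -> ExperimentConfig:
    return ExperimentConfig.preset("ci")


@pytest.fixture(scope="session")
def ci_network(ci_config):
    return build_al_network(ci_config.al_config(), seed=NET_SEED)


@pytest.fixture(scope="session")
def mb_connectivity(ci_config):
    return build_mb_connectivity(
        ci_config.n_pn, ci_config.n_kc, ci_config.n_mbon, seed=MB_SEED
    )


@pytest.fixture(scope="session")
def trial_bank(ci_config, ci_network):
    """Callable ``bank(sigma, odor_name, n)`` -> list of PreparedTrial."""
    cache: dict = {}

    def bank(sigma: float, name: str = "A", n: int = 2):
        trials = cache.setdefault((sigma, name), [])
        if len(trials) < n:
            odor = ci_config.odor(sigma, SHIFTS[name], label=name)
            seeds = _child_seeds(
                TRIAL_SEED, n, salt=int(sigma * 1000) + int(SHIFTS[name])
            )
            for i in range(len(trials), n):
                trials.append(
                    prepare_trial(ci_network, odor, ci_config, seeds[i], trial_index=i)
                )
        return trials[:n]

    return bank


@pytest.fixture(scope="session")
def phi_grid(ci_config):
    return np.asarray(ci_config.phi_grid)
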