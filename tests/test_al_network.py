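import numpy as np
import pytest

from locustolf.al_network import (
    ALConfig,
    GABA_KINETICS,
    NACH_KINETICS,
    LNParams,
    PNParams,
    SpikeTable,
    SynapseState,
    build_al_network,
    integrate_al,
    ionic_current,
    steady_state_gates,
    transmitter,
    update_calcium,
    update_synapse,
)
from locustolf.experiments import two_cell_pair_frequency
from locustolf.stimulus import OdorSpec, StimulusProtocol, StimulusTrial


def dc_trial(n_pn, n_ln, amp_pn, amp_ln, plateau=600.0):
    proto = StimulusProtocol(
        rise_ms=10.0, plateau_ms=plateau, decay_ms=50.0, noise_frac=1e-9
    )
    odor = OdorSpec(
        peak_index=0, sigma=10.0, amplitude=max(amp_pn, amp_ln, 1e-9), threshold_frac=0.0
    )
    return StimulusTrial(
        odor=odor,
        pn_amplitudes=np.full(n_pn, float(amp_pn)),
        ln_amplitudes=np.full(n_ln, float(amp_ln)),
        protocol=proto,
        seed=0,
    )


def isolated_config(**kw):
    return ALConfig(
        n_pn=1, n_ln=1, n_exc_pn=0, p_pn_ln=0.0, p_ln_pn=0.0, p_ln_ln=0.0,
        p_pn_pn=0.0, **kw
    )


class TestGateKinetics:
    @pytest.mark.parametrize(
        "v, gate, expected_inf",
        [
            (-60.0, "A_m", 0.5),
            (-78.0, "A_h", 0.5),
            (-20.0, "Ca_m", 0.5),
        ],
    )
    def test_half_activation_points(self, v, gate, expected_inf):
        x_inf, tau = steady_state_gates(v, gate)
        assert x_inf == pytest.approx(expected_inf, abs=1e-12)
        assert tau > 0

    def test_kca_gate_from_calcium(self):
        x_inf, tau = steady_state_gates(2.0, "KCa_m")
        assert x_inf == pytest.approx(0.5)
        assert tau == pytest.approx(25.0)

    def test_unknown_gate_rejected(self):
        with pytest.raises(ValueError):
            steady_state_gates(-60.0, "Nope")

    def test_gates_bounded_and_rates_finite_on_grid(self):
        """All steady states in [0,1], taus positive, including at the
        removable singularities of the rate expressions."""
        v = np.concatenate([np.linspace(-120, 60, 3601), [-42.0, -15.0, -30.0]])
        for gate in ("Na_m", "Na_h", "K_n", "A_m", "A_h", "Ca_m", "Ca_h"):
            x_inf, tau = steady_state_gates(v, gate)
            assert np.all(np.isfinite(x_inf)) and np.all(np.isfinite(tau))
            assert np.all((x_inf >= 0) & (x_inf <= 1))
            assert np.all(tau > 0)


class TestIonicCurrents:
    def test_zero_conductance_gives_zero(self):
        pn = PNParams(g_na=0.0)
        assert ionic_current("Na", -30.0, {"m": 0.5, "h": 0.5}, pn) == 0.0

    def test_zero_driving_force(self):
        pn = PNParams()
        assert ionic_current("Na", pn.e_na, {"m": 0.9, "h": 0.9}, pn) == 0.0

    def test_potassium_direct_evaluation(self):
        pn = PNParams()
        assert ionic_current("K", -95.0, {"n": 0.5}, pn) == 0.0
        # g_K * n^4 * (V - E_K) = 10 * 0.0625 * 20
        assert ionic_current("K", -75.0, {"n": 0.5}, pn) == pytest.approx(12.5)

    def test_unknown_current_rejected(self):
        with pytest.raises(ValueError):
            ionic_current("Cl", -60.0, {}, PNParams())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PNParams(g_na=-1.0)
        with pytest.raises(ValueError):
            LNParams(e_ca=200.0)


class TestCalcium:
    def test_fixed_point_without_current(self):
        ln = LNParams()
        assert update_calcium(ln.ca_inf, 0.0, 1.0, ln) == pytest.approx(ln.ca_inf)

    def test_linear_relaxation_efold(self):
        ln = LNParams()
        ca = update_calcium(1.0, 0.0, ln.tau_ca, ln)
        assert ca - ln.ca_inf == pytest.approx((1.0 - ln.ca_inf) * np.exp(-1), rel=1e-9)

    def test_inward_current_raises_calcium(self):
        ln = LNParams()
        assert update_calcium(ln.ca_inf, -10.0, 0.1, ln) > ln.ca_inf

    def test_positive_dt_required(self):
        with pytest.raises(ValueError):
            update_calcium(1.0, 0.0, 0.0)


class TestSynapseKinetics:
    def test_open_fraction_decays_without_transmitter(self):
        state = SynapseState(o=0.8, kinetics=NACH_KINETICS)
        o, t = state.o, 0.0
        for _ in range(100):
            state = update_synapse(state, t_since_pre_spike=1e9, dt=0.1)
            t += 0.1
        assert state.o == pytest.approx(0.8 * np.exp(-NACH_KINETICS.beta * t), rel=1e-6)

    def test_constant_transmitter_fixed_point(self):
        k = GABA_KINETICS
        state = SynapseState(o=0.0, kinetics=k)
        for _ in range(2000):
            state = update_synapse(state, v_pre=k.v0, dt=0.1)  # [T] = 0.5
        expected = k.alpha * 0.5 / (k.alpha * 0.5 + k.beta)
        assert state.o == pytest.approx(expected, rel=1e-6)

    def test_nach_transmitter_pulse(self):
        assert transmitter(NACH_KINETICS, t_since_pre_spike=0.1) == 0.5
        assert transmitter(NACH_KINETICS, t_since_pre_spike=0.5) == 0.0
        assert transmitter(NACH_KINETICS, t_since_pre_spike=-0.1) == 0.0


class TestNetworkConstruction:
    def test_determinism_from_seed(self):
        cfg = ALConfig(n_pn=40, n_ln=12, n_exc_pn=6)
        a = build_al_network(cfg, seed=9)
        b = build_al_network(cfg, seed=9)
        assert np.array_equal(a.a_pn_ln, b.a_pn_ln)
        assert np.array_equal(a.a_ln_pn, b.a_ln_pn)
        assert np.array_equal(a.exc_pn_idx, b.exc_pn_idx)
        c = build_al_network(cfg, seed=10)
        assert not np.array_equal(a.a_pn_ln, c.a_pn_ln)

    def test_zero_probability_empty_adjacency(self):
        net = build_al_network(isolated_config(), seed=0)
        assert not net.a_pn_ln.any() and not net.a_ln_pn.any()

    def test_excitatory_pn_subset(self):
        cfg = ALConfig(n_pn=350, n_ln=100, n_exc_pn=50)
        net = build_al_network(cfg, seed=3)
        assert len(net.exc_pn_idx) == 50
        # only the excitatory subset sends PN->PN connections
        senders = np.nonzero(net.a_pn_pn.any(axis=0))[0]
        assert set(senders) <= set(net.exc_pn_idx)
        assert not np.diag(net.a_pn_pn).any()
        assert not np.diag(net.a_ln_ln).any()

    def test_impossible_topology_rejected(self):
        with pytest.raises(ValueError):
            ALConfig(n_pn=10, n_exc_pn=11)
        with pytest.raises(ValueError):
            ALConfig(p_pn_ln=1.5)


class TestSpikeTable:
    def test_sorting_and_roundtrip(self, tmp_path):
        t = SpikeTable(
            neuron_ids=[2, 0, 1], times=[5.0, 1.0, 3.0], population="PN",
            n_neurons=3, duration=10.0,
        )
        assert list(t.times) == [1.0, 3.0, 5.0]
        assert list(t.neuron_ids) == [0, 1, 2]
        path = tmp_path / "spikes.csv"
        t.to_csv(path)
        back = SpikeTable.from_csv(path, n_neurons=3, duration=10.0)
        assert np.allclose(back.times, t.times)
        assert np.array_equal(back.neuron_ids, t.neuron_ids)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpikeTable([0], [11.0], "PN", 3, 10.0)
        with pytest.raises(ValueError):
            SpikeTable([3], [1.0], "PN", 3, 10.0)


class TestIntegration:
    def test_rest_without_input(self):
        """Energy-free rest: no input, no noise -> no spikes, V settles."""
        net = build_al_network(isolated_config(), seed=0)
        traj = integrate_al(net, None, duration=500.0, seed=0)
        assert len(traj.pn_spikes) == 0 and len(traj.ln_spikes) == 0
        tail = traj.lfp[-int(50 / traj.dt):]
        assert np.ptp(tail) < 0.1

    def test_gates_stay_bounded_during_drive(self):
        net = build_al_network(isolated_config(), seed=0)
        traj = integrate_al(
            net, dc_trial(1, 1, 9.0, 6.0), duration=400.0, seed=0,
            backend="numpy", store_v=True,
        )
        assert np.all(np.isfinite(traj.v_pn)) and np.all(np.isfinite(traj.v_ln))
        assert np.abs(traj.v_pn).max() < 200 and np.abs(traj.v_ln).max() < 200

    def test_ln_spike_frequency_adaptation(self):
        """Isolated LN under DC: inter-spikelet intervals do not shrink as
        KCa-mediated adaptation builds."""
        net = build_al_network(isolated_config(), seed=0)
        traj = integrate_al(net, dc_trial(1, 1, 0.0, 9.0, plateau=1500.0),
                            duration=1600.0, seed=0)
        isis = np.diff(traj.ln_spikes.times)
        assert len(isis) >= 8
        assert np.all(np.diff(isis[:10]) >= -1.0)
        assert isis[min(9, len(isis) - 1)] >= isis[0]

    def test_two_cell_pair_oscillates_near_20hz(self):
        r = two_cell_pair_frequency()
        assert 40.0 <= r["period_ms"] <= 60.0
        assert r["n_bursts"] >= 10

    def test_dt_convergence_of_spike_times(self):
        """Halving dt moves PN spike times by < 0.5 ms on a reference trial."""
        cfg = ALConfig(
            n_pn=1, n_ln=1, n_exc_pn=0, p_pn_ln=1.0, p_ln_pn=1.0,
            p_ln_ln=0.0, p_pn_pn=0.0, g_pn_ln=0.3, g_ln_pn=1.0,
        )
        net = build_al_network(cfg, seed=0)
        trial = dc_trial(1, 1, 9.0, 6.0, plateau=900.0)
        a = integrate_al(net, trial, duration=1000.0, dt=0.02, seed=0)
        b = integrate_al(net, trial, duration=1000.0, dt=0.01, seed=0)
        # the scheme is first order, so spike-phase drift accumulates over
        # the trial; the bound is checked over the first 250 ms
        ta = a.pn_spikes.times[a.pn_spikes.times < 250.0]
        tb = b.pn_spikes.times[b.pn_spikes.times < 250.0]
        n = min(len(ta), len(tb))
        assert n > 10
        assert abs(len(ta) - len(tb)) <= 1
        assert np.max(np.abs(ta[:n] - tb[:n])) < 0.5

    def test_backends_agree_on_short_horizon(self):
        """The compiled kernel and the numpy reference loop implement the
        same update scheme (trajectories agree before chaotic divergence)."""
        # a tonically spiking isolated PN: non-chaotic, so the two
        # backends must track each other over the whole trial
        net = build_al_network(isolated_config(), seed=2)
        trial = dc_trial(1, 1, 6.0, 0.0, plateau=180.0)
        a = integrate_al(net, trial, duration=200.0, seed=1, backend="numpy")
        b = integrate_al(net, trial, duration=200.0, seed=1, backend="numba")
        assert np.allclose(a.lfp, b.lfp, atol=1e-6)
        assert len(a.pn_spikes) == len(b.pn_spikes) > 20
        assert np.allclose(a.pn_spikes.times, b.pn_spikes.times, atol=0.021)

    def test_divergence_guard(self):
        with pytest.raises(ValueError):
            net = build_al_network(isolated_config(), seed=0)
            integrate_al(net, None, duration=100.0, dt=0.1)
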