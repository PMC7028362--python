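import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from locustolf.al_network import SpikeTable
from locustolf.mb_network import build_mb_connectivity
from locustolf.plasticity import (
    STDPParams,
    TraceState,
    decay_traces,
    on_post_spike,
    on_pre_spike,
    pair_delta_w,
    run_mbon_layer_plastic,
    train,
)

P = STDPParams()


class TestTraces:
    def test_single_efold(self):
        tr = TraceState(x=P.a_plus, y=0.0)
        out = decay_traces(tr, P.tau_plus, P)
        assert out.x == pytest.approx(P.a_plus * np.exp(-1))

    def test_zero_stays_zero(self):
        out = decay_traces(TraceState(0.0, 0.0), 5.0, P)
        assert out.x == 0.0 and out.y == 0.0

    def test_semigroup_property(self):
        tr = TraceState(x=1.3, y=0.7)
        once = decay_traces(tr, 8.0, P)
        twice = decay_traces(decay_traces(tr, 4.0, P), 4.0, P)
        assert once.x == pytest.approx(twice.x, rel=1e-12)
        assert once.y == pytest.approx(twice.y, rel=1e-12)

    def test_positive_dt_required(self):
        with pytest.raises(ValueError):
            decay_traces(TraceState(1.0, 1.0), 0.0, P)


class TestSpikeUpdates:
    def test_no_depression_without_post_trace(self):
        w, tr = on_pre_spike(1.0, TraceState(x=0.0, y=0.0), P)
        assert w == 1.0
        assert tr.x == P.a_plus

    def test_soft_bound_at_zero_weight(self):
        w, _ = on_pre_spike(0.0, TraceState(x=0.0, y=5.0), P)
        assert w == 0.0

    def test_soft_bound_at_max_weight(self):
        w, _ = on_post_spike(P.w_max, TraceState(x=5.0, y=0.0), P)
        assert w == P.w_max

    def test_no_potentiation_without_pre_trace(self):
        w, tr = on_post_spike(1.0, TraceState(x=0.0, y=0.0), P)
        assert w == 1.0
        assert tr.y == P.a_minus

    @pytest.mark.parametrize("delta_t", [2.0, 10.0, 35.0])
    def test_pre_before_post_potentiates(self, delta_t):
        """Event-driven pair: pre at 0, post at delta_t; the weight change
        matches the closed-form soft-bounded STDP kernel exactly."""
        w0 = 0.8
        _, tr = on_pre_spike(w0, TraceState(0.0, 0.0), P)
        tr = decay_traces(tr, delta_t, P)
        w1, _ = on_post_spike(w0, tr, P)
        expected = pair_delta_w(w0, delta_t, P)
        assert expected > 0
        assert w1 - w0 == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("delta_t", [-2.0, -10.0, -35.0])
    def test_post_before_pre_depresses(self, delta_t):
        w0 = 0.8
        _, tr = on_post_spike(w0, TraceState(0.0, 0.0), P)
        tr = decay_traces(tr, -delta_t, P)
        w1, _ = on_pre_spike(w0, tr, P)
        expected = pair_delta_w(w0, delta_t, P)
        assert expected < 0
        assert w1 - w0 == pytest.approx(expected, abs=1e-12)

    def test_kernel_magnitude_decays_with_lag(self):
        mags_pot = [pair_delta_w(1.0, dt, P) for dt in (1.0, 5.0, 20.0, 60.0)]
        mags_dep = [abs(pair_delta_w(1.0, -dt, P)) for dt in (1.0, 5.0, 20.0, 60.0)]
        assert all(a > b for a, b in zip(mags_pot, mags_pot[1:]))
        assert all(a > b for a, b in zip(mags_dep, mags_dep[1:]))

    @given(
        w=st.floats(0.0, 2.0),
        x=st.floats(0.0, 10.0),
        y=st.floats(0.0, 10.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_weights_stay_in_bounds(self, w, x, y):
        tr = TraceState(x=x, y=y)
        w1, _ = on_pre_spike(w, tr, P)
        w2, _ = on_post_spike(w, tr, P)
        assert P.w_min <= w1 <= P.w_max
        assert P.w_min <= w2 <= P.w_max


class TestHomeostasis:
    def test_balanced_fixed_point_location(self):
        # (W_max - w) eta+ a+ = w eta- a-  =>  w* = W_max/2 for defaults
        assert P.balanced_fixed_point == pytest.approx(P.w_max / 2)

    def test_symmetric_pairing_converges_to_fixed_point(self):
        """Alternating tight pre/post and post/pre pairs drive any initial
        weight toward the balanced fixed point."""
        for w0 in (0.1, 1.9):
            w = w0
            for _ in range(3000):
                # pre then post (potentiation), separate pair events
                _, tr = on_pre_spike(w, TraceState(0.0, 0.0), P)
                tr = decay_traces(tr, 1.0, P)
                w, _ = on_post_spike(w, tr, P)
                # post then pre (depression)
                _, tr = on_post_spike(w, TraceState(0.0, 0.0), P)
                tr = decay_traces(tr, 1.0, P)
                w, _ = on_pre_spike(w, tr, P)
            assert w == pytest.approx(P.balanced_fixed_point, abs=0.02)


class TestTraining:
    def make_conn(self, w_init=1.0):
        return build_mb_connectivity(10, 40, 4, seed=3, w_init=w_init)

    def silent_trial(self, n_kc=40):
        return SpikeTable(np.array([], dtype=int), np.array([]), "KC", n_kc, 200.0)

    def test_silent_schedule_leaves_weights_unchanged(self):
        conn = self.make_conn()
        post, hist = train(conn, [self.silent_trial()] * 3)
        assert np.array_equal(post.weights, conn.weights)
        assert hist.changed_mask.sum() == 0

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            train(self.make_conn(), [])

    def test_training_is_deterministic(self):
        conn = self.make_conn()
        rng = np.random.default_rng(0)
        ids = rng.integers(0, 40, 300)
        ts = np.sort(rng.uniform(0, 200.0, 300))
        trial = SpikeTable(ids, ts, "KC", 40, 200.0)
        p1, h1 = train(conn, [trial] * 4)
        p2, h2 = train(conn, [trial] * 4)
        assert np.array_equal(p1.weights, p2.weights)
        assert np.allclose(h1.median_trajectory, h2.median_trajectory)
        assert h1.changed_mask.sum() > 0

    def test_weights_bounded_through_online_training(self):
        conn = self.make_conn(w_init=1.9)
        rng = np.random.default_rng(1)
        ids = rng.integers(0, 40, 500)
        ts = np.sort(rng.uniform(0, 200.0, 500))
        trial = SpikeTable(ids, ts, "KC", 40, 200.0)
        _, w, _ = run_mbon_layer_plastic(trial, conn, STDPParams())
        on = w[conn.kc_mbon_mask]
        assert on.min() >= P.w_min and on.max() <= P.w_max
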