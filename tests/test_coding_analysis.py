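import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from locustolf.al_network import SpikeTable
from locustolf.coding_analysis import (
    BinaryPattern,
    binarize,
    distance_matrix,
    embed_and_classify,
    paired_comparison,
    pattern_distance,
)
from locustolf.lfp_gating import LFPTrace, filter_and_phase


def make_phase(duration_ms=600.0):
    t = np.arange(0, duration_ms, 0.05)
    x = np.sin(2 * np.pi * 20.0 * t / 1000.0)
    return filter_and_phase(LFPTrace(x, 0.05), window=(100.0, duration_ms - 50.0))


def pat(matrix, label=""):
    m = np.asarray(matrix, dtype=np.int8)
    bounds = np.arange(m.shape[1] + 1) * 50.0
    return BinaryPattern(matrix=m, cycle_bounds=bounds, label=label)


binary_matrices = arrays(
    np.int8, (6, 8), elements=st.integers(0, 1)
)


class TestBinarize:
    def test_no_spikes_all_zero(self):
        ps = make_phase()
        spikes = SpikeTable(np.array([], dtype=int), np.array([]), "MBON", 5, 600.0)
        p = binarize(spikes, ps)
        assert p.matrix.shape == (5, ps.n_cycles)
        assert not p.matrix.any()

    def test_one_spike_per_cycle_all_ones(self):
        ps = make_phase()
        mids = (ps.cycle_bounds[:-1] + ps.cycle_bounds[1:]) / 2
        ids = np.repeat(np.arange(3), len(mids))
        times = np.tile(mids, 3)
        p = binarize(SpikeTable(ids, times, "MBON", 3, 600.0), ps)
        assert p.matrix.all()

    def test_binarization_idempotence(self):
        ps = make_phase()
        t0 = ps.cycle_bounds[2] + 5.0
        spikes = SpikeTable([1, 1, 1], [t0, t0 + 1, t0 + 2], "MBON", 4, 600.0)
        p = binarize(spikes, ps)
        assert p.matrix.sum() == 1
        assert p.matrix[1, 2] == 1

    def test_out_of_range_spikes_ignored(self):
        ps = make_phase()
        spikes = SpikeTable([0, 0], [1.0, 599.0], "MBON", 2, 600.0)
        p = binarize(spikes, ps)
        assert p.matrix.sum() == 0

    def test_requires_cycles(self):
        ps = make_phase()
        object.__setattr__(ps, "cycle_bounds", ps.cycle_bounds[:1])
        spikes = SpikeTable([0], [100.0], "MBON", 2, 600.0)
        with pytest.raises(ValueError):
            binarize(spikes, ps)


class TestPatternDistance:
    def test_identity_and_single_flip(self):
        m = np.zeros((4, 5), dtype=int)
        assert pattern_distance(pat(m), pat(m)) == 0.0
        m2 = m.copy()
        m2[2, 3] = 1
        assert pattern_distance(pat(m), pat(m2)) == 1.0

    def test_complementary_patterns(self):
        m = np.zeros((4, 5), dtype=int)
        assert pattern_distance(pat(m), pat(1 - m)) == 20.0

    def test_truncation_to_common_cycles(self):
        a = pat(np.ones((3, 6), dtype=int))
        b = pat(np.zeros((3, 4), dtype=int))
        assert pattern_distance(a, b) == 12.0

    def test_mbon_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pattern_distance(pat(np.zeros((3, 4))), pat(np.zeros((4, 4))))

    @given(a=binary_matrices, b=binary_matrices)
    @settings(deadline=None, max_examples=100)
    def test_hamming_equals_squared_euclidean(self, a, b):
        d = pattern_distance(pat(a), pat(b))
        sq_euclid = float(np.sum((a.astype(float) - b.astype(float)) ** 2))
        assert d == sq_euclid

    @given(a=binary_matrices, b=binary_matrices, c=binary_matrices)
    @settings(deadline=None, max_examples=100)
    def test_metric_axioms(self, a, b, c):
        pa, pb, pc = pat(a), pat(b), pat(c)
        dab = pattern_distance(pa, pb)
        assert dab >= 0
        assert dab == pattern_distance(pb, pa)
        assert (dab == 0) == np.array_equal(a, b)
        assert dab <= pattern_distance(pa, pc) + pattern_distance(pc, pb)

    def test_normalized_variant(self):
        m = np.zeros((4, 5), dtype=int)
        assert pattern_distance(pat(m), pat(1 - m), normalized=True) == 1.0


class TestEmbedAndClassify:
    def test_two_tight_clusters_classified_perfectly(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.05, (10, 2)), rng.normal(5, 0.05, (10, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = [0] * 10 + [1] * 10
        _, mis = embed_and_classify(d, labels, seed=0)
        assert mis == 0

    def test_two_point_embedding_preserves_distance(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        coords, _ = embed_and_classify(d, [0, 1], seed=1)
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(3.0, rel=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            embed_and_classify(np.zeros((4, 4)), [0, 0, 1, 1])
        with pytest.raises(ValueError):
            embed_and_classify(np.eye(3), [0, 1, 0])  # nonzero diagonal
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            embed_and_classify(d, [0, 0])  # single class

    def test_distance_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        pats = [pat(rng.integers(0, 2, (5, 6))) for _ in range(4)]
        d = distance_matrix(pats)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)


class TestPairedComparison:
    def test_identical_samples(self):
        md, t, p = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert md == 0.0 and t == 0.0 and p == 1.0

    def test_textbook_example(self):
        # differences (1, 2, 3): mean 2, sd 1 -> t = 2 sqrt(3), df = 2
        md, t, p = paired_comparison([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert md == pytest.approx(2.0)
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert 0 < p < 0.1

    def test_sign_flip_negates_t(self):
        pre = [0.0, 0.0, 0.0]
        post = [1.0, 2.0, 3.0]
        _, t1, p1 = paired_comparison(pre, post)
        _, t2, p2 = paired_comparison(post, pre)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_nonzero_difference_rejected(self):
        with pytest.raises(ValueError):
            paired_comparison([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])

    def test_shape_checks(self):
        with pytest.raises(ValueError):
            paired_comparison([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_comparison([1.0, 2.0], [1.0, 2.0, 3.0])
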