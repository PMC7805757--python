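import numpy as np
import pytest

from hvgh.gp import (
    GPClassModel,
    KernelParams,
    UnknownSegmentError,
    build_gram,
    kernel,
)

from conftest import make_gp_model
from oracle import oracle_predict, oracle_segment_loglik


class TestKernel:
    def test_equal_positions_sum_coefficients(self, kp):
        assert kernel(1, 1, kp) == pytest.approx(17.0)

    def test_offset_positions(self, kp):
        assert kernel(1, 2, kp) == pytest.approx(np.exp(-0.5) + 32, abs=1e-12)

    def test_rbf_term_vanishes_at_large_distance(self):
        p = KernelParams(theta0=1.0, theta1=1.0, theta2=0.0, theta3=0.0, omega=1.0)
        assert kernel(1, 10**6, p) == pytest.approx(0.0, abs=1e-300)

    def test_symmetry(self, kp, rng):
        ip, iq = rng.integers(1, 50, size=2)
        assert kernel(ip, iq, kp) == pytest.approx(kernel(iq, ip, kp))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(omega=0.0)
        with pytest.raises(ValueError):
            KernelParams(theta0=-1.0)


class TestGram:
    def test_single_index(self, kp):
        C = build_gram([1], kp)
        assert C == pytest.approx(np.array([[17.1]]))

    def test_two_indices(self, kp):
        C = build_gram([1, 2], kp)
        expect = np.array([[17.1, np.exp(-0.5) + 32], [np.exp(-0.5) + 32, 65.1]])
        np.testing.assert_allclose(C, expect, atol=1e-12)

    def test_symmetric(self, kp, rng):
        idx = rng.integers(1, 30, size=8)
        C = build_gram(idx, kp)
        np.testing.assert_allclose(C, C.T)

    def test_empty_rejected(self, kp):
        with pytest.raises(ValueError):
            build_gram([], kp)


class TestPredict:
    def test_empty_model_prior_predictive(self, kp):
        m = GPClassModel(0, 2, kp, max_points=None)
        p = m.predict(3)
        np.testing.assert_allclose(p.mean, 0.0)
        np.testing.assert_allclose(p.variance, kernel(3, 3, kp))

    def test_noise_free_limit_interpolates(self):
        kp = KernelParams(omega=1e6)
        m = make_gp_model([[[5.0]]], kp)
        assert m.predict(1).mean[0] == pytest.approx(5.0, abs=1e-3)

    def test_single_point_hand_worked(self, kp):
        m = make_gp_model([[[5.0]]], kp)
        p = m.predict(1)
        assert p.mean[0] == pytest.approx(17 * 5 / 17.1, abs=1e-10)
        assert p.variance[0] == pytest.approx(17 - 17**2 / 17.1, abs=1e-10)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_dense_explicit_inverse(self, kp, trial):
        """GP predictive agrees with a from-scratch explicit-inverse
        computation on random training sets of up to 50 points."""
        rng = np.random.default_rng(100 + trial)
        n = rng.integers(1, 51)
        d = rng.integers(1, 4)
        idx = []
        while len(idx) < n:  # positions restart per segment, repeats allowed
            run = rng.integers(1, 8)
            idx.extend(range(1, run + 1))
        idx = idx[:n]
        vals = rng.normal(0.0, 2.0, (n, d))
        m = GPClassModel(0, d, kp, max_points=None)
        # feed data through the segment interface preserving positions
        pos = 0
        while pos < n:
            run = 1
            while pos + run < n and idx[pos + run] == idx[pos] + run:
                run += 1
            m.add_segment(vals[pos : pos + run])
            pos += run
        i_hat = int(rng.integers(1, 12))
        got = m.predict(i_hat)
        theta = (kp.theta0, kp.theta1, kp.theta2, kp.theta3)
        want_mean, want_var = oracle_predict(m.index_vector, m.value_matrix, i_hat, theta, kp.omega)
        np.testing.assert_allclose(got.mean, want_mean, atol=1e-8)
        np.testing.assert_allclose(got.variance, np.full(d, want_var), atol=1e-8)

    def test_one_factorization_serves_all_dimensions(self, kp, rng):
        """Per-dimension predictions from the shared factor equal
        independent single-dimension dense solves."""
        vals = rng.normal(size=(6, 3))
        m = make_gp_model([vals], kp, latent_dim=3)
        got = m.predict(4)
        theta = (kp.theta0, kp.theta1, kp.theta2, kp.theta3)
        for d in range(3):
            mean_d, _ = oracle_predict(
                m.index_vector, vals[:, [d]], 4, theta, kp.omega
            )
            assert got.mean[d] == pytest.approx(mean_d[0], abs=1e-8)

    def test_optional_noise_in_predictive(self, kp):
        plain = make_gp_model([[[1.0]]], kp)
        noisy = make_gp_model([[[1.0]]], kp, include_noise_in_predictive=True)
        dv = noisy.predict(1).variance[0] - plain.predict(1).variance[0]
        assert dv == pytest.approx(1.0 / kp.omega, abs=1e-12)


class TestSegmentLoglik:
    def test_empty_segment_is_zero(self, kp):
        m = make_gp_model([[[1.0]]], kp)
        assert m.segment_loglik(np.empty((0, 1))) == 0.0

    def test_single_point_equals_predict_density(self, kp):
        m = make_gp_model([[[1.0], [2.0]]], kp)
        p = m.predict(1)
        z = 0.7
        expect = -0.5 * np.log(2 * np.pi * p.variance[0]) - (z - p.mean[0]) ** 2 / (
            2 * p.variance[0]
        )
        assert m.segment_loglik([[z]]) == pytest.approx(expect)

    def test_matching_segment_beats_sign_flipped(self, kp):
        seg = np.array([[1.0], [2.0], [1.5]])
        m = make_gp_model([seg], kp)
        assert m.segment_loglik(seg) > m.segment_loglik(-seg)

    def test_additive_over_positions(self, kp, rng):
        seg = rng.normal(size=(4, 2))
        m = make_gp_model([rng.normal(size=(5, 2))], kp, latent_dim=2)
        total = m.segment_loglik(seg)
        theta = (kp.theta0, kp.theta1, kp.theta2, kp.theta3)
        want = oracle_segment_loglik(m.index_vector, m.value_matrix, seg, theta, kp.omega)
        assert total == pytest.approx(want, abs=1e-8)

    def test_permutation_invariant_across_dimensions(self, kp, rng):
        train = rng.normal(size=(5, 3))
        seg = rng.normal(size=(3, 3))
        perm = [2, 0, 1]
        m1 = make_gp_model([train], kp, latent_dim=3)
        m2 = make_gp_model([train[:, perm]], kp, latent_dim=3)
        assert m1.segment_loglik(seg) == pytest.approx(m2.segment_loglik(seg[:, perm]))


class TestDataManagement:
    def test_positions_restart_per_segment(self, kp):
        m = GPClassModel(0, 1, kp, max_points=None)
        m.add_segment(np.zeros((3, 1)))
        np.testing.assert_array_equal(m.index_vector, [1, 2, 3])
        m.add_segment(np.ones((2, 1)))
        np.testing.assert_array_equal(m.index_vector, [1, 2, 3, 1, 2])

    def test_two_segments_concatenate(self, kp):
        m = GPClassModel(0, 1, kp, max_points=None)
        m.add_segment(np.zeros((2, 1)))
        m.add_segment(np.ones((2, 1)))
        np.testing.assert_array_equal(m.index_vector, [1, 2, 1, 2])
        assert m.value_matrix.shape == (4, 1)

    def test_add_then_remove_restores_state(self, kp, rng):
        m = make_gp_model([rng.normal(size=(3, 1))], kp)
        before_i = m.index_vector.copy()
        before_t = m.value_matrix.copy()
        h = m.add_segment(rng.normal(size=(4, 1)))
        m.remove_segment(h)
        np.testing.assert_array_equal(m.index_vector, before_i)
        np.testing.assert_array_equal(m.value_matrix, before_t)

    def test_unknown_handle_raises(self, kp):
        m = GPClassModel(0, 1, kp)
        with pytest.raises(UnknownSegmentError):
            m.remove_segment(99)

    def test_cap_subsamples_training_set(self, kp):
        m = GPClassModel(0, 1, kp, max_points=10, rng=np.random.default_rng(0))
        m.add_segment(np.arange(40, dtype=float).reshape(-1, 1))
        m.refresh()
        assert m._i_c.size == 10
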