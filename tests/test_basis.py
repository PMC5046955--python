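"""Granular-layer processing: recoding, alpha filters, whitening."""

import numpy as np
import pytest

from cerebdea import (
    AlphaBasis,
    DecorrelationMatrix,
    InputRecoder,
    alpha_kernel,
    estimate_decorrelation,
    log_spaced_time_constants,
)

SIGMA = np.array([2.18, 2.48, 2.78, 3.08, 3.38])


class TestInputRecoder:
    def test_rectification_against_published_thresholds(self):
        recoder = InputRecoder(nu=5, sigma=SIGMA)
        q = recoder(3.08)
        np.testing.assert_allclose(q, [3.08, 0.90, 0.60, 0.30, 0.0, 0.0],
                                   atol=1e-12)

    def test_all_below_threshold(self):
        recoder = InputRecoder(nu=5, sigma=SIGMA)
        np.testing.assert_array_equal(recoder(0.0), np.zeros(6))

    def test_linear_passthrough(self):
        recoder = InputRecoder(nu=0)
        np.testing.assert_array_equal(recoder(2.5), [2.5])

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            InputRecoder(nu=3, sigma=np.array([1.0, 0.5, 2.0]))
        with pytest.raises(ValueError):
            InputRecoder(nu=2, sigma=np.array([1.0]))


class TestAlphaKernel:
    def test_log_spaced_time_constants(self):
        T = log_spaced_time_constants(0.1, 0.5, 4)
        np.testing.assert_allclose(T, [0.1, 0.17100, 0.29240, 0.5], atol=5e-5)

    def test_starts_at_zero_and_peaks_at_T(self):
        T, dt = 0.2, 0.001  # fine sampling to locate the continuous peak
        h = alpha_kernel(T, dt, horizon=2.0)
        assert h[0] == 0.0
        assert np.argmax(h) * dt == pytest.approx(T, abs=2 * dt)

    def test_unit_dc_gain(self):
        h = alpha_kernel(0.1, 0.02, horizon=3.0)
        assert h.sum() == pytest.approx(1.0, abs=1e-9)

    def test_truncation_warning(self):
        with pytest.warns(UserWarning, match="truncates"):
            alpha_kernel(0.5, 0.02, horizon=1.0)


class TestAlphaBasis:
    def test_zero_input(self):
        basis = AlphaBasis(T=np.array([0.1, 0.5]), dt=0.02, n_channels=2)
        for _ in range(10):
            np.testing.assert_array_equal(basis.step(np.zeros(2)), np.zeros(4))

    def test_dc_gain(self):
        basis = AlphaBasis(T=np.array([0.1, 0.5]), dt=0.02, n_channels=1)
        for _ in range(4000):
            g = basis.step(np.array([1.7]))
        np.testing.assert_allclose(g, 1.7, atol=1e-9)

    def test_matches_direct_convolution(self):
        # recursive bank == brute-force convolution with the alpha kernel
        T = log_spaced_time_constants(0.1, 0.5, 4)
        basis = AlphaBasis(T=T, dt=0.02, n_channels=1)
        rng = np.random.default_rng(11)
        x = rng.standard_normal(500)
        got = np.array([basis.step(np.array([xi])) for xi in x])
        for i, Ti in enumerate(T):
            h = alpha_kernel(Ti, 0.02, horizon=60.0 * Ti)
            oracle = np.convolve(x, h)[: len(x)]
            np.testing.assert_allclose(got[:, i], oracle, atol=1e-10)

    def test_channel_major_ordering(self):
        # impulse on channel 1 only must appear in outputs n_f..2*n_f-1
        basis = AlphaBasis(T=np.array([0.1, 0.3]), dt=0.02, n_channels=2)
        basis.step(np.array([0.0, 1.0]))
        g = basis.step(np.array([0.0, 0.0]))
        assert np.all(g[:2] == 0)
        assert np.all(g[2:] > 0)


class TestDecorrelation:
    def test_white_batch_gives_orthogonal_q(self):
        rng = np.random.default_rng(0)
        batch = rng.standard_normal((5000, 4))
        dec = estimate_decorrelation(batch)
        # Q is (approximately) orthogonal for an already-white batch
        np.testing.assert_allclose(dec.Q @ dec.Q.T, np.eye(4), atol=0.1)

    def test_diagonal_covariance_closed_form(self):
        rng = np.random.default_rng(1)
        batch = rng.standard_normal((200000, 2)) * np.array([np.sqrt(2.0),
                                                             np.sqrt(0.5)])
        dec = estimate_decorrelation(batch)
        np.testing.assert_allclose(np.abs(dec.Q),
                                   np.diag([1 / np.sqrt(2), np.sqrt(2)]),
                                   atol=0.02)

    def test_whitening_postcondition(self):
        # cov of the transformed batch is the identity within 1e-6
        rng = np.random.default_rng(2)
        mix = rng.standard_normal((6, 6))
        batch = rng.standard_normal((4000, 6)) @ mix.T
        dec = estimate_decorrelation(batch, floor_rel=1e-12)
        white = batch @ dec.Q.T
        np.testing.assert_allclose(np.cov(white.T), np.eye(6), atol=1e-6)

    def test_near_degenerate_channel_warns(self):
        rng = np.random.default_rng(3)
        batch = rng.standard_normal((2000, 3))
        batch[:, 2] = 1e-12 * batch[:, 2]
        with pytest.warns(UserWarning, match="near-zero-variance"):
            estimate_decorrelation(batch, floor_rel=1e-6)

    def test_unfitted_q_raises(self):
        dec = DecorrelationMatrix(Q=np.eye(2), mean=np.zeros(2), fitted=False)
        with pytest.raises(RuntimeError):
            dec(np.zeros(2))

    def test_linearity_and_identity(self):
        dec = DecorrelationMatrix.identity(3)
        g = np.array([1.0, -2.0, 0.5])
        np.testing.assert_array_equal(dec(g), g)

    def test_whitening_accelerates_lms(self):
        # eigenvalue-spread argument: with a correlated basis, LMS at its
        # stable rate crawls along weak directions; whitening equalises the
        # modes so the same problem converges in far fewer samples
        rng = np.random.default_rng(7)
        mix = np.array([[1.0, 0.95, 0.9],
                        [0.0, 0.1, 0.2],
                        [0.0, 0.0, 0.05]])
        X = rng.standard_normal((20000, 3)) @ mix
        # target weight along the weakest covariance eigenvector (hard case)
        evals, evecs = np.linalg.eigh(np.cov(X.T))
        w_star = evecs[:, np.argmin(evals)]
        d = X @ w_star
        dec = estimate_decorrelation(X, floor_rel=1e-12)

        def samples_to_converge(Z, target):
            lam_max = np.linalg.eigvalsh(np.cov(Z.T)).max()
            rate = 0.5 / lam_max  # same stability-normalised rate for both
            w = np.zeros(3)
            d0 = np.mean(d**2)
            for k in range(len(Z)):
                err = w @ Z[k] - d[k]
                w -= rate * err * Z[k]
                if k % 50 == 49 and np.mean((Z @ w - d) ** 2) < 0.1 * d0:
                    return k
            return len(Z)

        n_raw = samples_to_converge(X, w_star)
        n_white = samples_to_converge(X @ dec.Q.T, None)
        assert n_white < n_raw
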