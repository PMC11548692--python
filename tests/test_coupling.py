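import numpy as np
import pytest
from scipy.stats import pearsonr

from cardiocouple.coupling import (
    CouplingSolveConfig,
    build_convolution_matrix,
    couple_segment,
    deconvolve,
    deconvolve_full,
    pad_to_full,
    prepare_target,
)
from cardiocouple.io_preprocess import SegmentTriplet, zscore
from cardiocouple.synthetic import SynthConfig, synth_record


class TestConvolutionMatrix:
    def test_delta_input_gives_identity(self):
        np.testing.assert_array_equal(build_convolution_matrix([1, 0]), np.eye(3))

    def test_ones_pair_enumerated(self):
        expected = np.array([[1, 0, 1], [1, 1, 0], [0, 1, 1]], dtype=float)
        np.testing.assert_array_equal(build_convolution_matrix([1, 1]), expected)

    def test_first_column_is_padded_input(self, rng):
        x = rng.standard_normal(5)
        C = build_convolution_matrix(x)
        np.testing.assert_array_equal(C[:, 0], pad_to_full(x))

    def test_matvec_equals_linear_convolution(self, rng):
        x = rng.standard_normal(5)
        C = build_convolution_matrix(x)
        for _ in range(20):
            h = rng.standard_normal(5)
            got = C @ np.concatenate([h, np.zeros(4)])
            np.testing.assert_allclose(got, np.convolve(x, h), atol=1e-12)


class TestPrepareTarget:
    def test_example(self):
        np.testing.assert_array_equal(prepare_target([3, 1]), [3, 1, 0])

    def test_prefix_preserved(self, rng):
        y = rng.standard_normal(17)
        out = prepare_target(y)
        assert len(out) == 33
        np.testing.assert_array_equal(out[:17], y)
        assert not out[17:].any()

    def test_zero_in_zero_out(self):
        assert not prepare_target(np.zeros(4)).any()


class TestDeconvolve:
    def test_identity_system(self):
        h = deconvolve(np.array([1.0, 0.0]), np.array([2.0, 4.0, 0.0]),
                       CouplingSolveConfig(reg_lambda=0))
        np.testing.assert_allclose(h, [2.0, 4.0], atol=1e-12)

    def test_hand_convolution_instance(self):
        # y = conv([1,1],[1,2]) = [1,3,2]; cross-check against the dense solve
        x = np.array([1.0, 1.0])
        y = np.array([1.0, 3.0, 2.0])
        h = deconvolve(x, y, CouplingSolveConfig(reg_lambda=0))
        np.testing.assert_allclose(h, [1.0, 2.0], atol=1e-10)
        dense = np.linalg.solve(build_convolution_matrix(x), y)
        np.testing.assert_allclose(h, dense[:2], atol=1e-10)

    def test_random_instances_recover_kernel(self, rng):
        n_ok = 0
        for _ in range(50):
            N = int(rng.integers(4, 65))
            x = rng.standard_normal(N)
            spec = np.abs(np.fft.fft(pad_to_full(x)))
            if spec.min() < 1e-6 * spec.max():
                continue
            h_true = rng.standard_normal(N)
            y = np.convolve(x, h_true)
            h = deconvolve(x, y, CouplingSolveConfig(reg_lambda=0))
            assert np.linalg.norm(h - h_true) <= 1e-8 * np.linalg.norm(h_true)
            n_ok += 1
        assert n_ok >= 40  # nearly all random spectra are well conditioned

    def test_spectral_matches_direct_solver(self, rng):
        for reg in (0.0, 1e-3, 1e-1):
            x = rng.standard_normal(64)
            y = rng.standard_normal(127)
            hs = deconvolve_full(x, y, CouplingSolveConfig(reg, "spectral"))
            hd = deconvolve_full(x, y, CouplingSolveConfig(reg, "direct"))
            assert np.linalg.norm(hs - hd) <= 1e-8 * np.linalg.norm(hd)

    def test_reconstruction_improves_as_reg_shrinks(self, rng):
        x = rng.standard_normal(32)
        y = rng.standard_normal(63)
        C = build_convolution_matrix(x)
        errs = []
        for reg in (1e-1, 1e-2, 1e-3, 1e-6):
            h = deconvolve_full(x, y, CouplingSolveConfig(reg))
            errs.append(np.linalg.norm(C @ h - y) / np.linalg.norm(y))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-4

    def test_linearity_in_target(self, rng):
        x = rng.standard_normal(24)
        y1, y2 = rng.standard_normal((2, 47))
        cfg = CouplingSolveConfig(1e-3)
        lhs = deconvolve(x, 2.0 * y1 - 3.0 * y2, cfg)
        rhs = 2.0 * deconvolve(x, y1, cfg) - 3.0 * deconvolve(x, y2, cfg)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_degenerate_input(self):
        with pytest.raises(ValueError, match="degenerate input"):
            deconvolve(np.zeros(4), np.zeros(7))

    def test_ill_conditioned_without_regularization(self):
        x = np.array([1.0, -1.0])  # zero-sum input: exact DC spectral zero
        with pytest.raises(ValueError, match="ill-conditioned"):
            deconvolve(x, np.ones(3), CouplingSolveConfig(reg_lambda=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CouplingSolveConfig(reg_lambda=-1)
        with pytest.raises(ValueError):
            CouplingSolveConfig(solver="magic")


class TestCoupleSegment:
    def _ecg_segment(self, N=2000, K=100):
        rec = synth_record(SynthConfig(duration_s=12, noise_sd=0.02), "s", 0, 123)
        ecg = rec.ecg[1000 : 1000 + N].copy()
        ecg[-K:] = 0.0  # keep the kernel's convolution tail inside the window
        ecg = zscore(ecg)
        ecg[-K:] = 0.0
        return ecg

    def test_known_kernel_recovery(self):
        N, K = 2000, 100
        ecg = self._ecg_segment(N, K)
        t = np.arange(K)
        kernel = np.sin(2 * np.pi * t / 17) * np.exp(-t / 25.0)
        pcg = zscore(np.convolve(ecg, kernel)[:N])
        seg = SegmentTriplet("s", 0, ecg, pcg)
        out = couple_segment(seg, CouplingSolveConfig(1e-3))
        assert len(out.coupling_seg) == N
        ktrue = np.concatenate([kernel, np.zeros(N - K)])
        assert pearsonr(out.coupling_seg, ktrue).statistic >= 0.95

    def test_self_coupling_is_delta_at_lag_zero(self):
        ecg = self._ecg_segment()
        seg = SegmentTriplet("s", 0, ecg, ecg)
        out = couple_segment(seg, CouplingSolveConfig(1e-3))
        assert int(np.argmax(out.coupling_seg)) == 0

    def test_zero_variance_coupling_raises(self):
        ecg = self._ecg_segment()
        seg = SegmentTriplet("s", 0, ecg, np.zeros_like(ecg))
        with pytest.raises(ValueError, match="zero variance"):
            couple_segment(seg)
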