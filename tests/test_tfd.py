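import numpy as np
import pytest

from conftest import make_segment, reference_separable_tfd
from hiegrade.tfd import (
    TfdKernelParams,
    analytic_associate,
    prewhiten,
    separable_tfd,
    trim_and_log,
    wvd_full,
)


class TestPrewhiten:
    def test_constant_input_gives_zeros(self):
        out = prewhiten(np.full(100, 3.7))
        assert np.allclose(out, 0)

    def test_ramp_gives_constant_slope(self):
        out = prewhiten(0.25 * np.arange(200, dtype=float))
        assert np.allclose(out[:-1], 0.25)
        assert out[-1] == 0.0

    def test_sinusoid_gain_matches_first_difference_closed_form(self):
        fs, f0 = 64.0, 8.0
        n = 4097  # n - 1 samples hold an integer cycle count: no leakage
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * f0 * t)
        out = prewhiten(x)
        expected_gain = 2 * np.sin(np.pi * f0 / fs)
        spec = np.abs(np.fft.rfft(out[:-1]))
        freqs = np.fft.rfftfreq(n - 1, 1 / fs)
        peak = spec.max() / ((n - 1) / 2)
        assert freqs[spec.argmax()] == pytest.approx(f0, abs=0.05)
        assert peak == pytest.approx(expected_gain, rel=1e-3)

    def test_length_preserved_on_segment(self):
        seg = make_segment(np.random.default_rng(0).normal(size=19_200))
        out = prewhiten(seg)
        assert out.n_times == 19_200


class TestAnalyticAssociate:
    def test_cosine_becomes_complex_exponential(self):
        fs, f0, n = 64.0, 8.0, 1024
        t = np.arange(n) / fs
        z = analytic_associate(np.cos(2 * np.pi * f0 * t)).values
        assert np.allclose(z, np.exp(2j * np.pi * f0 * t), atol=1e-6)

    def test_zero_input_zero_output(self):
        assert np.allclose(analytic_associate(np.zeros(64)).values, 0)

    def test_negative_frequencies_suppressed_and_energy_doubled(self, rng):
        x = rng.normal(size=512)
        spec_x = np.fft.rfft(x)
        spec_x[0] = spec_x[-1] = 0  # DC and Nyquist are not doubled
        x = np.fft.irfft(spec_x)
        z = analytic_associate(x).values
        spec = np.fft.fft(z)
        neg = np.abs(spec[257:]) ** 2
        assert neg.sum() < 1e-10 * (np.abs(spec) ** 2).sum()
        assert np.real(z) == pytest.approx(x, abs=1e-9)
        # Parseval: the analytic signal doubles the strictly-positive-band
        # energy of the real signal
        assert np.sum(np.abs(z) ** 2) == pytest.approx(2 * np.sum(x**2), rel=1e-6)


class TestWvdFull:
    def test_impulse_concentrates_at_its_time_slice(self):
        z = np.zeros(64, complex)
        z[20] = 1.0
        w = wvd_full(z)
        assert np.allclose(w[20], 1.0 / 64)  # flat over frequency
        w[20] = 0
        assert np.allclose(w, 0, atol=1e-12)

    def test_tone_ridge_at_tone_frequency(self):
        fs, f0, n = 64.0, 10.0, 256
        t = np.arange(n) / fs
        z = np.exp(2j * np.pi * f0 * t)
        w = wvd_full(z)
        # frequency axis: bin k -> k * fs / (2N)
        expected_bin = int(round(f0 * 2 * n / fs))
        assert np.all(w[10:-10].argmax(axis=1) == expected_bin)

    def test_energy_conserved(self, rng):
        z = rng.normal(size=128) + 1j * rng.normal(size=128)
        w = wvd_full(z)
        assert w.sum() == pytest.approx(np.sum(np.abs(z) ** 2), rel=1e-10)

    def test_refuses_oracle_scale_violation(self):
        with pytest.raises(ValueError, match="reference"):
            wvd_full(np.zeros(4096, complex))


class TestSeparableTfd:
    @pytest.mark.parametrize(
        "n,params",
        [
            (64, TfdKernelParams(15, 15, 32, 16)),
            (128, TfdKernelParams(31, 15, 64, 32)),
        ],
    )
    def test_matches_brute_force_oracle(self, rng, n, params):
        z = rng.normal(size=n) + 1j * rng.normal(size=n)
        fast = separable_tfd(z, params)
        ref = reference_separable_tfd(z, params)
        assert np.max(np.abs(fast - ref)) < 1e-8 * np.max(np.abs(ref))

    def test_default_params_give_256_by_128(self):
        rng = np.random.default_rng(3)
        z = analytic_associate(rng.normal(size=19_200)).values
        out = separable_tfd(z)
        assert out.shape == (256, 128)

    def test_pure_tone_localises_within_one_bin(self):
        fs, f0 = 64.0, 10.0
        t = np.arange(19_200) / fs
        z = analytic_associate(np.cos(2 * np.pi * f0 * t)).values
        out = separable_tfd(z)
        peak_bins = out[5:-5].argmax(axis=1)
        bin_hz = 32.0 / 128
        assert np.all(np.abs(peak_bins * bin_hz - f0) <= bin_hz)

    def test_realness_with_symmetric_windows(self, rng):
        # the implementation returns the real part; verify the imaginary
        # part it discards is numerically zero via the complex oracle
        z = rng.normal(size=64) + 1j * rng.normal(size=64)
        params = TfdKernelParams(15, 15, 32, 16)
        ref = reference_separable_tfd(z, params)  # .real applied inside
        fast = separable_tfd(z, params)
        assert np.allclose(fast, ref, atol=1e-10 * np.max(np.abs(ref)))

    def test_energy_conserved_on_full_grid(self, rng):
        z = rng.normal(size=64) + 1j * rng.normal(size=64)
        rho = separable_tfd(z, TfdKernelParams(15, 15, 64, 64))
        assert rho.sum() == pytest.approx(np.sum(np.abs(z) ** 2), rel=1e-9)

    def test_energy_on_decimated_grid_within_decimation_factor(self, rng):
        # sampling every d-th time slice and every d-th frequency bin keeps
        # ~1/(d_t * d_f) of the energy; rescaling by the strides recovers
        # the total up to the decimation approximation
        z = rng.normal(size=256) + 1j * rng.normal(size=256)
        rho = separable_tfd(z, TfdKernelParams(31, 31, 64, 64))
        stride_t = stride_f = 256 // 64
        total = np.sum(np.abs(z) ** 2)
        assert rho.sum() * stride_t * stride_f == pytest.approx(total, rel=0.2)

    def test_degenerate_allpass_kernel_reduces_to_wvd(self, rng):
        # boxcar windows spanning the whole (odd-N) grid apply no
        # smoothing, so the separable TFD collapses to the plain WVD
        n = 63
        z = rng.normal(size=n) + 1j * rng.normal(size=n)
        params = TfdKernelParams(n, n, n, n, window="boxcar")
        assert np.allclose(separable_tfd(z, params), wvd_full(z), atol=1e-10)

    def test_rejects_even_windows_and_oversize_windows(self):
        with pytest.raises(ValueError, match="odd"):
            TfdKernelParams(doppler_len=16, lag_len=15)
        with pytest.raises(ValueError, match="longer"):
            TfdKernelParams(doppler_len=65, lag_len=15, n_time=32, n_freq=16)
        with pytest.raises(ValueError, match="divisible"):
            separable_tfd(np.zeros(100, complex), TfdKernelParams(15, 15, 32, 16))


class TestTrimAndLog:
    def test_128_bins_trim_to_112(self, rng):
        out = trim_and_log(rng.normal(size=(256, 128)))
        assert out.shape == (256, 112)
        assert out.freq_offset_hz == pytest.approx(2.0)

    def test_all_zero_matrix_floors_finite(self):
        out = trim_and_log(np.zeros((256, 128)))
        assert np.all(np.isfinite(out.values))
        assert np.allclose(out.values, np.log(1e-12))

    def test_scaling_shifts_by_log_factor(self, rng):
        m = np.abs(rng.normal(size=(256, 128))) + 0.1
        a = trim_and_log(m).values
        b = trim_and_log(10 * m).values
        assert np.allclose(b - a, np.log(10), atol=1e-9)

    def test_misaligned_cut_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            trim_and_log(rng.normal(size=(256, 128)), low_cut_hz=2.1)
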