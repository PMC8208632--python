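import numpy as np
import pytest
from scipy import fft as sfft

from hiegrade.preprocess import EegRecording, EegSegment


def embed_window(w: np.ndarray, length: int) -> np.ndarray:
    """Place a window on a length-L circular axis, centred at the origin."""
    half = (len(w) - 1) // 2
    out = np.zeros(length)
    for i, b in enumerate(range(-half, half + 1)):
        out[b % length] += w[i]
    return out


def reference_separable_tfd(z, params) -> np.ndarray:
    """Brute-force oracle: full-grid WVD, ambiguity-domain kernel, decimate.

    Materialises the full N x N plane (the route the fast path avoids):
    instantaneous autocorrelation over all lags folded mod N, Doppler
    smoothing by FFT over time, lag windowing, FFT over lag, then plain
    row/column sampling down to the n_time x n_freq grid.
    """
    z = np.asarray(z, complex).ravel()
    N = z.size
    zp = np.concatenate([np.zeros(N, complex), z, np.zeros(N, complex)])
    K = np.zeros((N, N), complex)
    for m in range(-(N - 1), N):
        K[:, m % N] += zp[N + m : 2 * N + m] * np.conj(zp[N - m : 2 * N - m])
    A = sfft.fft(K, axis=0)  # Doppler spectrum along time
    g = embed_window(params.doppler_window(), N)
    h = embed_window(params.lag_window(), N)
    S = sfft.ifft(A * g[:, None], axis=0) * h[None, :]
    rho = sfft.fft(S, axis=1).real / N
    return rho[:: N // params.n_time, :: N // params.n_freq]


def brute_force_artifact_mask(env, fs, thr1, collar1, thr2, collar2):
    """Sample-by-sample two-stage mask for ONE channel (no hemisphere
    spread): stage 1 collars around every env > thr1 sample, stage 2
    collars around every thr2 < env <= thr1 sample."""
    n = env.size
    mask = np.zeros(n, dtype=bool)
    c1, c2 = int(round(collar1 * fs)), int(round(collar2 * fs))
    for i in range(n):
        if env[i] > thr1:
            mask[max(0, i - c1) : min(n, i + c1 + 1)] = True
        elif env[i] > thr2:
            mask[max(0, i - c2) : min(n, i + c2 + 1)] = True
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nine_electrode_recording(rng):
    """2-minute random recording on the 9 standard electrodes at 256 Hz."""
    labels = ["F4", "C4", "O2", "F3", "C3", "O1", "T4", "T3", "Cz"]
    fs = 256.0
    samples = rng.normal(scale=20.0, size=(9, int(120 * fs)))
    return EegRecording(samples=samples, fs=fs, channel_labels=labels)


def make_segment(x, fs=64.0, channel="F4-C4"):
    return EegSegment(samples=np.asarray(x, float), channel=channel, fs=fs)
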