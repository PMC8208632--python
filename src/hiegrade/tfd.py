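"""Separable-kernel quadratic time-frequency distribution of an EEG segment.

The Wigner-Ville distribution (WVD) of the analytic signal is smoothed by a
separable kernel applied multiplicatively in the Doppler-lag (ambiguity)
domain: a Hann window g(nu) over Doppler and a Hann window h(tau) over lag.
Because the windows are short, the smoothed distribution is band-limited in
Doppler and lag, so it can be sampled on a coarse n_time x n_freq grid with
no aliasing error.  The fast path below exploits this: it never materialises
the N x N time-frequency plane, touching only lag_len columns of the
instantaneous autocorrelation (O(lag_len * N) work, O(lag_len * n_time)
intermediate memory), yet it equals the full-grid computation sampled at the
coarse grid exactly (up to FFT round-off).

Conventions (normative for this package):

* instantaneous autocorrelation K[n, m] = z[n+m] z*[n-m] with integer lag m
  and zero padding beyond the record edges;
* frequency axis f_k = k * fs / (2 L) for a length-L DFT over lag, spanning
  [0, fs/2) for the analytic signal;
* windows are centred on the Doppler/lag origin and zero elsewhere;
* scaling such that the full-grid smoothed TFD with unit-peak windows
  satisfies sum(rho) = sum(|z|^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal as _signal
from scipy import fft as _fft
from scipy.signal import hilbert

from .preprocess import EegSegment

__all__ = [
    "TfdKernelParams",
    "TfdMatrix",
    "AnalyticSegment",
    "DEVELOPMENT_KERNEL",
    "VALIDATION_KERNEL",
    "prewhiten",
    "analytic_associate",
    "wvd_full",
    "separable_tfd",
    "trim_and_log",
    "tfd_pipeline",
]

_ORACLE_LIMIT = 1024


@dataclass(frozen=True)
class TfdKernelParams:
    """Separable Doppler-lag kernel and output-grid geometry.

    doppler_len, lag_len
        Odd sample counts of the Hann windows g(nu) and h(tau).  They are
        defined on the decimated Doppler/lag grids, so they must not exceed
        n_time and n_freq respectively (that bound is also what makes the
        decimated computation exact).
    n_time, n_freq
        Output grid: time slices and frequency bins before band trimming.
    window
        "hann" (default) or "boxcar"; boxcar exists for the degenerate
        no-smoothing limit used in verification.
    """

    doppler_len: int = 127
    lag_len: int = 63
    n_time: int = 256
    n_freq: int = 128
    window: str = "hann"

    def __post_init__(self) -> None:
        for name in ("doppler_len", "lag_len"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and positive, got {v}")
        if self.n_time < 2 or self.n_freq < 2:
            raise ValueError("output grid must have at least 2 points per axis")
        if self.doppler_len > self.n_time:
            raise ValueError(
                f"doppler window ({self.doppler_len}) longer than time grid "
                f"({self.n_time})"
            )
        if self.lag_len > self.n_freq:
            raise ValueError(
                f"lag window ({self.lag_len}) longer than frequency grid "
                f"({self.n_freq})"
            )
        if self.window not in ("hann", "boxcar"):
            raise ValueError(f"unknown window kind {self.window!r}")

    def doppler_window(self) -> np.ndarray:
        return _make_window(self.window, self.doppler_len)

    def lag_window(self) -> np.ndarray:
        return _make_window(self.window, self.lag_len)


#: kernel used to train on the development cohort
DEVELOPMENT_KERNEL = TfdKernelParams(doppler_len=127, lag_len=63)
#: kernel selected by grid search for the multi-centre validation run
VALIDATION_KERNEL = TfdKernelParams(doppler_len=123, lag_len=59)


@dataclass
class TfdMatrix:
    """Log-magnitude TFD image of one segment (256 x 112 by default)."""

    values: np.ndarray
    time_step_s: float
    freq_step_hz: float
    freq_offset_hz: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TFD image must be finite (log floor applied)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AnalyticSegment:
    """Complex analytic associate of a real segment."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex).ravel()

    @property
    def n_times(self) -> int:
        return self.values.size


def _make_window(kind: str, length: int) -> np.ndarray:
    if kind == "hann":
        # symmetric convention: endpoint zeros, unit peak at the centre
        return _signal.windows.hann(length, sym=True)
    return np.ones(length)


def _as_array(seg) -> np.ndarray:
    if isinstance(seg, EegSegment):
        return seg.samples
    if isinstance(seg, AnalyticSegment):
        return seg.values
    return np.asarray(seg).ravel()


def prewhiten(seg: EegSegment | np.ndarray) -> EegSegment | np.ndarray:
    """Forward first difference; spectrum-flattening pre-whitener.

    y[n] = x[n+1] - x[n]; the final sample is zero-padded to preserve
    length.  Differencing removes any constant (DC) component.
    """
    x = _as_array(seg)
    y = np.zeros_like(x, dtype=float)
    y[:-1] = np.diff(x)
    if isinstance(seg, EegSegment):
        return EegSegment(
            samples=y,
            channel=seg.channel,
            fs=seg.fs,
            epoch_id=seg.epoch_id,
            segment_index=seg.segment_index,
            channel_index=seg.channel_index,
        )
    return y


def analytic_associate(seg: EegSegment | np.ndarray) -> AnalyticSegment:
    """Analytic associate via the Hilbert transform (FFT method)."""
    x = _as_array(seg)
    if np.iscomplexobj(x):
        raise ValueError("analytic associate is defined for real signals")
    return AnalyticSegment(values=hilbert(x))


def _k_column(zp: np.ndarray, N: int, m: int) -> np.ndarray:
    """K[:, m] = z[n+m] z*[n-m] with zero padding outside [0, N)."""
    return zp[N + m : 2 * N + m] * np.conj(zp[N - m : 2 * N - m])


def wvd_full(z: AnalyticSegment | np.ndarray) -> np.ndarray:
    """Full-grid discrete Wigner-Ville distribution (reference; O(N^2)).

    Direct evaluation of the instantaneous autocorrelation over all lags
    folded modulo N, DFT over lag.  Scaled so that sum(W) = sum(|z|^2).
    Refuses long inputs: this is the brute-force reference, not the
    production path.
    """
    zv = _as_array(np.asarray(z.values) if isinstance(z, AnalyticSegment) else z)
    zv = np.asarray(zv, dtype=complex)
    N = zv.size
    if N > _ORACLE_LIMIT:
        raise ValueError(f"wvd_full is a reference implementation; N <= {_ORACLE_LIMIT}")
    zp = np.concatenate([np.zeros(N, complex), zv, np.zeros(N, complex)])
    K = np.zeros((N, N), dtype=complex)
    for m in range(-(N - 1), N):
        K[:, m % N] += _k_column(zp, N, m)
    W = _fft.fft(K, axis=1) / N
    return W.real


def separable_tfd(
    z: AnalyticSegment | np.ndarray, params: TfdKernelParams | None = None
) -> np.ndarray:
    """Decimated separable-kernel quadratic TFD (fast path).

    Equals the full-grid smoothed WVD sampled at the n_time x n_freq grid,
    computed without materialising the N x N plane.  Requires the signal
    length to be divisible by both grid dimensions.
    """
    if params is None:
        params = TfdKernelParams()
    zv = np.asarray(z.values if isinstance(z, AnalyticSegment) else z, dtype=complex)
    zv = zv.ravel()
    N = zv.size
    nt, nf = params.n_time, params.n_freq
    if N % nt or N % nf:
        raise ValueError(
            f"signal length {N} must be divisible by n_time={nt} and n_freq={nf}"
        )
    D = (params.doppler_len - 1) // 2
    M = (params.lag_len - 1) // 2
    if 2 * M + 1 > N or 2 * D + 1 > N:
        raise ValueError("kernel windows longer than the signal")
    g = params.doppler_window()
    h = params.lag_window()
    zp = np.concatenate([np.zeros(N, complex), zv, np.zeros(N, complex)])
    stride = N // nt

    # smoothed, time-decimated autocorrelation, one lag at a time:
    # peak intermediate memory O(lag_len * n_time) (+ the O(N) signal copies)
    s_dec = np.empty((nt, 2 * M + 1), dtype=complex)
    dop_bins = np.arange(-D, D + 1)
    fold = np.zeros(nt, dtype=complex)
    for j, m in enumerate(range(-M, M + 1)):
        col = _k_column(zp, N, m)
        A = _fft.fft(col)  # Doppler spectrum of lag m
        fold[:] = 0
        np.add.at(fold, dop_bins % nt, A[dop_bins % N] * g)
        s_dec[:, j] = _fft.ifft(fold) * (nt / N) * h[j]

    # fold lags modulo n_freq and DFT over lag
    lag_fold = np.zeros((nt, nf), dtype=complex)
    for j, m in enumerate(range(-M, M + 1)):
        lag_fold[:, m % nf] += s_dec[:, j]
    rho = _fft.fft(lag_fold, axis=1) / N
    return rho.real


def trim_and_log(
    tfd: np.ndarray,
    fs: float = 64.0,
    low_cut_hz: float = 2.0,
    high_cut_hz: float = 30.0,
    floor: float | None = None,
    meta: dict[str, Any] | None = None,
    duration_s: float = 300.0,
) -> TfdMatrix:
    """Drop wrap-around bands and compress to log magnitude.

    Bins with centres in [0, low_cut) and [high_cut, fs/2) Hz are removed
    (default: 8 + 8 of 128, leaving 112), then log(max(|v|, eps)) is taken
    with eps = 1e-12 * max(|v|) (or 1 if the matrix is all zero).
    """
    tfd = np.asarray(tfd, dtype=float)
    n_time, n_freq = tfd.shape
    step = (fs / 2) / n_freq
    lo = low_cut_hz / step
    hi = high_cut_hz / step
    if abs(lo - round(lo)) > 1e-9 or abs(hi - round(hi)) > 1e-9:
        raise ValueError(
            f"cut frequencies {low_cut_hz}/{high_cut_hz} Hz do not land on the "
            f"{step} Hz bin grid"
        )
    lo_i, hi_i = int(round(lo)), int(round(hi))
    kept = tfd[:, lo_i:hi_i]
    mags = np.abs(kept)
    if floor is None:
        peak = mags.max()
        floor = 1e-12 * (peak if peak > 0 else 1.0)
    values = np.log(np.maximum(mags, floor))
    return TfdMatrix(
        values=values,
        time_step_s=duration_s / n_time,
        freq_step_hz=step,
        freq_offset_hz=lo_i * step,
        meta=dict(meta or {}),
    )


def tfd_pipeline(
    seg: EegSegment, params: TfdKernelParams | None = None
) -> TfdMatrix:
    """Segment -> pre-whiten -> analytic -> separable TFD -> trim/log."""
    if params is None:
        params = TfdKernelParams()
    white = prewhiten(seg)
    z = analytic_associate(white)
    raw = separable_tfd(z, params)
    meta = {
        "channel": seg.channel,
        "epoch_id": seg.epoch_id,
        "segment_index": seg.segment_index,
        "channel_index": seg.channel_index,
        "doppler_len": params.doppler_len,
        "lag_len": params.lag_len,
    }
    return trim_and_log(
        raw, fs=seg.fs, meta=meta, duration_s=seg.n_times / seg.fs
    )
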