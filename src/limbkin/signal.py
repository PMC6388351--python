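"""Signal conditioning and dual-device alignment.

Zero-phase Butterworth low-pass filtering of angle waveforms, upsampling of
both devices onto a common dense grid, cross-correlation lag estimation to
remove the unknown clock offset between devices, and time normalization to
a fixed number of points for waveform statistics.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .errors import DomainError, SamplingError, SeriesLengthError, UndefinedStatisticError
from .types import WaveformPair

DEFAULT_CUTOFF_HZ = 6.0     #: low-pass cut-off used for both devices
DEFAULT_RESAMPLE_HZ = 300.0  #: common dense grid for synchronization
DEFAULT_MAX_LAG_S = 2.0     #: half-width of the lag search window
PERCENT_POINTS = 101        #: samples of a time-normalized waveform (0..100 %)


def lowpass(series: np.ndarray, fs: float, cutoff: float = DEFAULT_CUTOFF_HZ,
            order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    ``order`` is the effective order after the forward-backward pass (a
    half-order causal filter applied twice), following the common practice
    in movement analysis.  DC gain is exactly 1 and the output has the
    input's length.
    """
    series = np.asarray(series, dtype=float)
    if not (fs > 2 * cutoff):
        raise SamplingError(f"fs = {fs} must exceed twice the cutoff ({cutoff} Hz)")
    if order < 2 or order % 2:
        raise DomainError("order must be an even integer >= 2")
    if series.shape[-1] < 3 * order:
        raise SeriesLengthError(f"series too short to filter (need >= {3 * order} samples)")
    b, a = butter(order // 2, cutoff / (fs / 2.0))
    return filtfilt(b, a, series, axis=-1)


def resample_to(series: np.ndarray, fs_in: float, fs_out: float = DEFAULT_RESAMPLE_HZ) -> np.ndarray:
    """Upsample a uniform series onto a denser uniform grid.

    Cubic-spline interpolation over the original time span; the output grid
    starts at the first input sample and steps at ``1/fs_out``, so the input
    endpoints are preserved within one output sample.  Downsampling is not
    supported (it would require an explicit anti-aliasing decision).
    """
    series = np.asarray(series, dtype=float)
    if not (fs_in > 0 and fs_out > 0):
        raise DomainError("sampling rates must be > 0")
    if fs_out < fs_in:
        raise SamplingError("resample_to only upsamples; fs_out must be >= fs_in")
    n_in = series.shape[-1]
    if n_in < 2:
        raise SeriesLengthError("need at least 2 samples to resample")
    if fs_out == fs_in:
        return series.copy()
    t_in = np.arange(n_in) / fs_in
    n_out = int(np.floor(t_in[-1] * fs_out)) + 1
    t_out = np.arange(n_out) / fs_out
    return CubicSpline(t_in, series, axis=-1)(t_out)


def estimate_lag(a: np.ndarray, b: np.ndarray, fs: float,
                 max_lag: float = DEFAULT_MAX_LAG_S) -> float:
    """Lag (seconds) by which ``b`` trails ``a``, from normalized cross-correlation.

    The lag maximizes the Pearson correlation of the overlapping segments
    over integer sample shifts within ``±max_lag`` (each segment is centred
    on its own mean, so truncating a plateau or ramp tail does not bias the
    peak).  Positive lag means ``b[t] ≈ a[t − lag]``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.allclose(a, a.mean()) or np.allclose(b, b.mean()):
        raise UndefinedStatisticError("cross-correlation undefined for a flat series")
    n_short = min(len(a), len(b))
    max_shift = int(round(max_lag * fs))
    if max_shift >= n_short // 2:
        raise DomainError("max_lag must be below half the shorter series duration")
    best_lag, best_val = 0, -np.inf
    for k in range(-max_shift, max_shift + 1):
        if k >= 0:  # b trails a by k samples: b[i + k] ~ a[i]
            xa, xb = a[: len(a) - k], b[k:]
        else:
            xa, xb = a[-k:], b[: len(b) + k]
        m = min(len(xa), len(xb))
        xa = xa[:m] - xa[:m].mean()
        xb = xb[:m] - xb[:m].mean()
        denom = np.linalg.norm(xa) * np.linalg.norm(xb)
        if denom == 0:
            continue
        val = float(xa @ xb) / denom
        if val > best_val:
            best_val, best_lag = val, k
    return best_lag / fs


def sync_by_crosscorr(a: np.ndarray, b: np.ndarray, fs: float,
                      max_lag: float = DEFAULT_MAX_LAG_S,
                      channel: str = "", lag: float | None = None) -> WaveformPair:
    """Align two same-rate waveforms by removing their estimated clock offset.

    Estimates the lag of ``b`` relative to ``a`` (or applies a caller-
    provided ``lag``, e.g. one estimated on a larger-excursion channel),
    shifts ``b`` back by that many samples and crops both to the overlap.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if lag is None:
        lag = estimate_lag(a, b, fs, max_lag)
    k = int(round(lag * fs))
    if k >= 0:
        a_al, b_al = a[: len(a)], b[k:]
    else:
        a_al, b_al = a[-k:], b
    m = min(len(a_al), len(b_al))
    if m < max(len(a), len(b)) * 0.5:
        raise DomainError("aligned overlap below half the series length")
    return WaveformPair(channel=channel, series_a=a_al[:m], series_b=b_al[:m],
                        fs=fs, lag_applied=k / fs)


def time_normalize(series: np.ndarray, n_points: int = PERCENT_POINTS) -> np.ndarray:
    """Linearly interpolate a series onto ``n_points`` spanning 0–100 % of its duration."""
    series = np.asarray(series, dtype=float)
    if n_points < 2:
        raise DomainError("n_points must be >= 2")
    n = series.shape[-1]
    if n < 2:
        raise SeriesLengthError("need at least 2 samples to time-normalize")
    x_new = np.linspace(0.0, n - 1.0, n_points)
    if series.ndim == 1:
        return np.interp(x_new, np.arange(n), series)
    return np.stack([np.interp(x_new, np.arange(n), row) for row in series])
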