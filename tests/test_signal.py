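"""Signal conditioning: filtering, resampling, lag estimation, normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from limbkin import estimate_lag, lowpass, resample_to, sync_by_crosscorr, time_normalize
from limbkin.errors import (
    DomainError,
    SamplingError,
    SeriesLengthError,
    UndefinedStatisticError,
)


# ---------------------------------------------------------------------------
# lowpass
# ---------------------------------------------------------------------------

def test_lowpass_dc_gain():
    x = np.full(500, 3.7)
    y = lowpass(x, fs=100.0)
    np.testing.assert_allclose(y, x, atol=1e-9)


def test_lowpass_attenuates_high_frequency():
    t = np.arange(0, 5, 0.01)
    x = np.sin(2 * np.pi * 1.0 * t) + 0.5 * np.sin(2 * np.pi * 25.0 * t)
    y = lowpass(x, fs=100.0, cutoff=6.0)
    resid = y - np.sin(2 * np.pi * 1.0 * t)
    assert np.sqrt(np.mean(resid[50:-50] ** 2)) < 0.02


def test_lowpass_zero_phase():
    t = np.arange(0, 5, 0.01)
    x = np.sin(2 * np.pi * 2.0 * t)
    y = lowpass(x, fs=100.0, cutoff=6.0)
    # the peak of a zero-phase filtered sinusoid does not shift
    assert abs(int(np.argmax(y[100:200])) - int(np.argmax(x[100:200]))) <= 1


def test_lowpass_guards():
    with pytest.raises(SamplingError):
        lowpass(np.zeros(100), fs=10.0, cutoff=6.0)
    with pytest.raises(SeriesLengthError):
        lowpass(np.zeros(5), fs=100.0)
    with pytest.raises(DomainError):
        lowpass(np.zeros(100), fs=100.0, order=3)


# ---------------------------------------------------------------------------
# resample_to
# ---------------------------------------------------------------------------

def test_resample_linear_ramp_exact():
    x = np.linspace(0.0, 1.0, 31)  # 1 s ramp at 30 Hz
    y = resample_to(x, 30.0, 300.0)
    t_out = np.arange(len(y)) / 300.0
    np.testing.assert_allclose(y, t_out, atol=1e-6)


def test_resample_sinusoid_accuracy():
    fs_in, fs_out = 30.0, 300.0
    t_in = np.arange(0, 3, 1 / fs_in)
    x = np.sin(2 * np.pi * 2.0 * t_in)
    y = resample_to(x, fs_in, fs_out)
    t_out = np.arange(len(y)) / fs_out
    assert np.max(np.abs(y - np.sin(2 * np.pi * 2.0 * t_out))) < 1e-3


def test_resample_preserves_endpoints():
    x = np.array([2.0, 5.0, 3.0, 7.0])
    y = resample_to(x, 10.0, 100.0)
    assert y[0] == pytest.approx(2.0, abs=1e-12)
    assert y[-1] == pytest.approx(7.0, abs=1e-9)


def test_resample_guards():
    with pytest.raises(SamplingError):
        resample_to(np.zeros(100), 100.0, 30.0)  # downsampling unsupported
    with pytest.raises(SeriesLengthError):
        resample_to(np.ones(1), 30.0, 300.0)
    with pytest.raises(DomainError):
        resample_to(np.zeros(10), -1.0, 300.0)


# ---------------------------------------------------------------------------
# estimate_lag / sync_by_crosscorr
# ---------------------------------------------------------------------------

def _plateau_ramp(fs, lag_s=0.0, dur=4.0):
    t = np.arange(0, dur, 1 / fs)
    tau = np.clip((t - 1.0 - lag_s) / 1.5, 0.0, 1.0)
    return tau ** 3 * (10 - 15 * tau + 6 * tau ** 2)


def test_lag_recovered_exactly():
    fs = 300.0
    a = _plateau_ramp(fs)
    b = _plateau_ramp(fs, lag_s=0.2)
    assert estimate_lag(a, b, fs, max_lag=1.0) == pytest.approx(0.2, abs=1 / fs + 1e-12)


def test_lag_recovered_under_noise():
    fs = 300.0
    rng = np.random.default_rng(8)
    a = _plateau_ramp(fs) + rng.normal(0, 0.005, 1200)
    b = _plateau_ramp(fs, lag_s=0.2) + rng.normal(0, 0.005, 1200)
    assert estimate_lag(a, b, fs, max_lag=1.0) == pytest.approx(0.2, abs=1 / fs + 1e-12)


def test_negative_lag():
    fs = 300.0
    a = _plateau_ramp(fs, lag_s=0.3)
    b = _plateau_ramp(fs)
    assert estimate_lag(a, b, fs, max_lag=1.0) == pytest.approx(-0.3, abs=1 / fs + 1e-12)


def test_lag_zero_for_identical():
    fs = 300.0
    a = _plateau_ramp(fs)
    assert estimate_lag(a, a, fs, max_lag=1.0) == 0.0


def test_lag_flat_series_undefined():
    with pytest.raises(UndefinedStatisticError):
        estimate_lag(np.ones(600), np.arange(600.0), 300.0)


def test_lag_window_guard():
    with pytest.raises(DomainError):
        estimate_lag(np.arange(100.0), np.arange(100.0), 100.0, max_lag=0.9)


def test_sync_crops_to_overlap():
    fs = 300.0
    a = _plateau_ramp(fs)
    b = _plateau_ramp(fs, lag_s=0.2)
    pair = sync_by_crosscorr(a, b, fs, max_lag=1.0, channel="shoulder_fe")
    assert pair.lag_applied == pytest.approx(0.2, abs=1 / fs + 1e-12)
    assert pair.series_a.shape == pair.series_b.shape
    # after alignment the two series coincide on the overlap
    assert np.sqrt(np.mean((pair.series_a - pair.series_b) ** 2)) < 1e-6


# ---------------------------------------------------------------------------
# time_normalize
# ---------------------------------------------------------------------------

def test_time_normalize_ramp():
    y = time_normalize(np.linspace(2.0, 4.0, 57), 101)
    np.testing.assert_allclose(y, np.linspace(2.0, 4.0, 101), atol=1e-12)


def test_time_normalize_constant():
    np.testing.assert_array_equal(time_normalize(np.full(33, 5.0), 101), np.full(101, 5.0))


def test_time_normalize_identity_on_matching_grid():
    x = np.sin(np.linspace(0, 3, 101))
    np.testing.assert_allclose(time_normalize(x, 101), x, atol=1e-12)


def test_time_normalize_guard():
    with pytest.raises(DomainError):
        time_normalize(np.arange(10.0), 1)
    with pytest.raises(SeriesLengthError):
        time_normalize(np.array([1.0]), 101)


@given(k=st.integers(-60, 60))
def test_lag_sign_property(k):
    """Shifting a symmetric pulse later by k samples yields lag +k/fs."""
    fs = 100.0
    t = np.arange(0, 6, 1 / fs)
    a = np.exp(-((t - 3.0) ** 2) / 0.5)
    b = np.exp(-((t - 3.0 - k / fs) ** 2) / 0.5)
    assert estimate_lag(a, b, fs, max_lag=1.0) == pytest.approx(k / fs, abs=1e-9)
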