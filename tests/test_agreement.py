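"""Agreement statistics against hand-computed and library oracles."""

import math

import numpy as np
import pytest

from limbkin import (
    Task,
    cmc,
    default_task,
    extract_pta,
    extract_rom,
    icc_3k,
    intersession_waveform_reliability,
    paired_validity,
)
from limbkin.agreement import pta_frame, rmse
from limbkin.errors import DomainError, UndefinedStatisticError
from limbkin.types import JointAngleSeries


# ---------------------------------------------------------------------------
# CMC
# ---------------------------------------------------------------------------

def test_cmc_identical_waveforms():
    w = np.sin(np.linspace(0, 3, 101))
    value, flag = cmc(np.stack([w, w]))
    assert value == pytest.approx(1.0, abs=1e-12)
    assert not flag


def test_cmc_hand_computed_positive():
    # Y1=(0,1,2), Y2=(0.5,1.5,2.5): num = 0.125/3, den = 4.375/5 hand-derived;
    # CMC = sqrt(1 - (0.375/3)/(4.375/5)) = 0.9258200997725515
    value, flag = cmc(np.array([[0.0, 1.0, 2.0], [0.5, 1.5, 2.5]]))
    assert not flag
    assert value == pytest.approx(0.9258200997725515, abs=1e-12)


def test_cmc_complex_case():
    # Y1=(0,1,2), Y2=(2,1,0): radicand = 1 - (4/3)/(4/5) = -2/3 -> flagged 0
    value, flag = cmc(np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]]))
    assert flag
    assert value == 0.0


def test_cmc_multi_trial_stack():
    rng = np.random.default_rng(1)
    base = np.sin(np.linspace(0, 3, 101))
    Y = np.stack([np.stack([base + rng.normal(0, 0.01, 101) for _ in range(2)])
                  for _ in range(5)])
    value, flag = cmc(Y)
    assert not flag
    assert value > 0.99


def test_cmc_guards():
    with pytest.raises(DomainError):
        cmc(np.zeros((1, 101)))  # single protocol
    with pytest.raises(DomainError):
        cmc(np.zeros((2, 2)))    # too few frames
    with pytest.raises(UndefinedStatisticError):
        cmc(np.ones((2, 101)))   # zero variance


# ---------------------------------------------------------------------------
# RMSE
# ---------------------------------------------------------------------------

def test_rmse_hand_computed():
    assert rmse(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == pytest.approx(
        math.sqrt(12.5), abs=1e-12)


def test_rmse_zero_for_identical():
    x = np.arange(10.0)
    assert rmse(x, x) == 0.0


def test_rmse_shape_guard():
    with pytest.raises(DomainError):
        rmse(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# PTA / ROM
# ---------------------------------------------------------------------------

def _series_with_peak():
    t = np.linspace(0, 2, 201)
    ang = np.zeros((201, 4))
    ang[:, 3] = 27.0 + 100.0 * np.sin(np.pi * t / 2.0) ** 2  # elbow peak at t=1 s
    ang[:, 0] = 10.0 * t
    return JointAngleSeries(time=t, angles=ang)


def test_pta_frame_finds_apex():
    series = _series_with_peak()
    task = default_task(Task.HAND_TO_MOUTH)  # primary channel: elbow
    idx = pta_frame(series, task)
    assert idx == 100  # apex of the out-and-back elbow excursion


def test_extract_pta_values():
    series = _series_with_peak()
    vals = extract_pta(series, default_task(Task.HAND_TO_MOUTH))
    assert vals[3] == pytest.approx(127.0, abs=1e-9)
    assert vals[0] == pytest.approx(10.0, abs=1e-9)  # shoulder at that instant


def test_extract_rom():
    series = _series_with_peak()
    rom = extract_rom(series)
    assert rom[3] == pytest.approx(100.0, abs=1e-9)
    assert rom[0] == pytest.approx(20.0, abs=1e-9)
    assert rom[1] == 0.0


def test_pta_respects_mask():
    series = _series_with_peak()
    series.valid[90:110, 3] = False  # mask the apex region
    idx = pta_frame(series, default_task(Task.HAND_TO_MOUTH))
    assert idx in (89, 110)


# ---------------------------------------------------------------------------
# paired validity
# ---------------------------------------------------------------------------

def test_paired_validity_hand_computed():
    # pairs (1,2),(2,4),(3,6): bias -2, r = 1, t = -2*sqrt(3) on 2 dof
    res = paired_validity(np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0]))
    assert res.bias == pytest.approx(-2.0, abs=1e-12)
    assert res.r == pytest.approx(1.0, abs=1e-9)
    assert res.p == pytest.approx(0.07417990022744854, abs=1e-12)
    assert res.n == 3
    assert not res.significant  # p > 0.01


def test_paired_validity_zero_variance_difference():
    res = paired_validity(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))
    assert res.bias == pytest.approx(1.0)
    assert math.isnan(res.p)
    assert not res.significant


def test_paired_validity_strong_bias_significant():
    rng = np.random.default_rng(2)
    ref = rng.normal(50, 10, 10)
    res = paired_validity(ref + 14.0 + rng.normal(0, 1, 10), ref)
    assert res.significant
    assert res.bias == pytest.approx(14.0, abs=1.5)


def test_paired_validity_guards():
    with pytest.raises(DomainError):
        paired_validity(np.zeros(2), np.zeros(2))
    with pytest.raises(DomainError):
        paired_validity(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_icc_identical_sessions():
    M = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
    res = icc_3k(M)
    assert res.consistency == pytest.approx(1.0, abs=1e-12)
    assert res.agreement == pytest.approx(1.0, abs=1e-12)


def test_icc_hand_computed():
    # rows (1,1),(2,2),(3,4): MS_B=19/6, MS_S=MS_E=1/6 -> both forms 18/19
    res = icc_3k(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 4.0]]))
    assert res.ms_between == pytest.approx(19.0 / 6.0, abs=1e-12)
    assert res.ms_sessions == pytest.approx(1.0 / 6.0, abs=1e-12)
    assert res.ms_error == pytest.approx(1.0 / 6.0, abs=1e-12)
    assert res.consistency == pytest.approx(18.0 / 19.0, abs=1e-12)
    assert res.agreement == pytest.approx(18.0 / 19.0, abs=1e-12)


def test_icc_against_pingouin():
    """Cross-check both ICC forms against the pingouin implementation."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(7)
    for _ in range(10):
        n, k = int(rng.integers(4, 12)), int(rng.integers(2, 4))
        M = rng.normal(0, 5, (n, 1)) + rng.normal(0, 1.5, (n, k))
        res = icc_3k(M)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "scores": M.ravel(),
        })
        table = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                         ratings="scores").set_index("Type")
        assert res.consistency == pytest.approx(table.loc["ICC(C,k)", "ICC"], abs=1e-10)
        assert res.agreement == pytest.approx(table.loc["ICC(A,k)", "ICC"], abs=1e-10)


def test_icc_variance_components_monte_carlo():
    """n=10, k=2, between-sd 10, within-sd 3: ICC stays in [0.85, 0.999]."""
    rng = np.random.default_rng(11)
    vals = []
    for _ in range(200):
        subj = rng.normal(0, 10, (10, 1))
        M = subj + rng.normal(0, 3, (10, 2))
        vals.append(icc_3k(M).consistency)
    vals = np.array(vals)
    assert np.mean((vals > 0.85) & (vals < 0.999)) > 0.9


def test_icc_guards():
    with pytest.raises(DomainError):
        icc_3k(np.zeros((2, 2)))
    with pytest.raises(UndefinedStatisticError):
        icc_3k(np.ones((5, 2)))


# ---------------------------------------------------------------------------
# intersession reliability
# ---------------------------------------------------------------------------

def test_intersession_identical():
    s = np.stack([np.sin(np.linspace(0, 3, 101)) for _ in range(5)])
    value, flag, err = intersession_waveform_reliability(s, s)
    assert value == pytest.approx(1.0, abs=1e-12)
    assert not flag
    assert err == 0.0


def test_intersession_detects_offset():
    s1 = np.stack([np.sin(np.linspace(0, 3, 101)) for _ in range(5)])
    s2 = s1 + 0.5
    value, flag, err = intersession_waveform_reliability(s1, s2)
    assert err == pytest.approx(0.5, abs=1e-12)
    assert value < 1.0
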