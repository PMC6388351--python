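"""Agreement and reliability statistics.

Waveform-level agreement (coefficient of multiple correlation, RMSE),
discrete-parameter agreement (angles at the point of target achieved, range
of motion, mean bias, Pearson r, paired t-tests), and test-retest
reliability (inter-session CMC/RMSE and intraclass correlation for averaged
measurements).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, PairingError, UndefinedStatisticError
from .types import CHANNELS, JointAngleSeries, TaskDefinition

ALPHA = 0.01  #: significance level used for the paired t-tests


# ---------------------------------------------------------------------------
# Waveform agreement
# ---------------------------------------------------------------------------

def cmc(waveforms: np.ndarray) -> tuple[float, bool]:
    """Inter-protocol coefficient of multiple correlation.

    ``waveforms`` is (P, F) — P protocols/devices/sessions by F time-
    normalized frames — or (G, P, F) for G trials.  Returns ``(value,
    complex_flag)``.  The statistic compares the residual variance about the
    per-frame across-protocol mean with the total variance about each
    trial's grand mean:

        CMC = sqrt(1 − [ΣΣΣ (Y_gpf − Ȳ_gf)² / (G·F·(P−1))]
                       / [ΣΣΣ (Y_gpf − Ȳ_g)² / (G·(P·F−1))])

    When the waveforms differ more than they vary, the radicand is negative
    ("complex CMC"); by convention the value 0.0 is returned with the flag
    set.
    """
    Y = np.asarray(waveforms, dtype=float)
    if Y.ndim == 2:
        Y = Y[None]
    if Y.ndim != 3:
        raise DomainError("waveforms must have shape (P, F) or (G, P, F)")
    G, P, F = Y.shape
    if P < 2 or F < 3:
        raise DomainError("need at least 2 protocols and 3 frames")
    if not np.all(np.isfinite(Y)):
        raise DomainError("waveforms contain non-finite values")

    frame_mean = Y.mean(axis=1, keepdims=True)        # Ȳ_gf
    grand_mean = Y.mean(axis=(1, 2), keepdims=True)   # Ȳ_g
    num = np.sum((Y - frame_mean) ** 2) / (G * F * (P - 1))
    den = np.sum((Y - grand_mean) ** 2) / (G * (P * F - 1))
    if den == 0:
        raise UndefinedStatisticError("zero total variance: CMC undefined")
    radicand = 1.0 - num / den
    if radicand < 0:
        return 0.0, True
    return float(np.sqrt(radicand)), False


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference between two equal-length series (degrees)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DomainError("series must have equal shape")
    if a.size < 1:
        raise DomainError("series must be non-empty")
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------------
# Discrete parameters
# ---------------------------------------------------------------------------

def pta_frame(series: JointAngleSeries, task: TaskDefinition, baseline_frac: float = 0.02) -> int:
    """Index of the point-of-target-achieved frame.

    The goal posture is located where the task's primary channel (elbow
    flexion for the two hand-to-body-target tasks, shoulder flexion/
    extension for the two large-excursion tasks) deviates most from its
    initial value — the final frame for a monotone reach, the apex for an
    out-and-back movement.
    """
    c = task.primary_channel
    x = series.angles[:, c]
    ok = series.valid[:, c]
    n0 = max(int(len(x) * baseline_frac), 1)
    baseline = np.nanmean(np.where(ok[:n0], x[:n0], np.nan))
    if not np.isfinite(baseline):
        raise UndefinedStatisticError("primary channel masked at trial start")
    dev = np.abs(x - baseline)
    dev[~ok] = -np.inf
    idx = int(np.argmax(dev))
    if not ok[idx]:
        raise UndefinedStatisticError("primary channel fully masked: PTA undefined")
    return idx


def extract_pta(series: JointAngleSeries, task: TaskDefinition) -> np.ndarray:
    """All four channel values (degrees) at the point-of-target-achieved frame."""
    idx = pta_frame(series, task)
    if not series.valid[idx, task.primary_channel]:
        raise UndefinedStatisticError("primary channel masked at the PTA frame")
    return series.angles[idx].copy()


def extract_rom(series: JointAngleSeries) -> np.ndarray:
    """Per-channel range of motion: max − min over the valid samples."""
    out = np.empty(4)
    for c in range(4):
        x = series.angles[series.valid[:, c], c]
        if x.size < 2:
            raise UndefinedStatisticError(f"channel {CHANNELS[c]} has < 2 valid samples")
        out[c] = x.max() - x.min()
    return out


# ---------------------------------------------------------------------------
# Paired-sample validity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedValidity:
    bias: float          # mean(test − reference)
    r: float             # Pearson correlation
    p: float             # two-sided paired t-test p-value (NaN if undefined)
    n: int
    significant: bool    # p < ALPHA


def paired_validity(test: np.ndarray, reference: np.ndarray, alpha: float = ALPHA) -> PairedValidity:
    """Mean bias, Pearson r and paired t-test for matched device measurements.

    ``test`` and ``reference`` are per-subject values (e.g. subject means of
    a PTA angle) from the two devices.  With zero variance in the paired
    differences the t statistic is undefined and ``p`` is reported as NaN.
    """
    x = np.asarray(test, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("paired samples must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise DomainError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("paired samples must be finite")
    bias = float(np.mean(x - y))
    if np.std(x) == 0 or np.std(y) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(x, y).statistic)
    d = x - y
    if np.std(d, ddof=1) == 0:
        p = np.nan
    else:
        p = float(stats.ttest_rel(x, y).pvalue)
    return PairedValidity(bias=bias, r=r, p=p, n=n, significant=bool(np.isfinite(p) and p < alpha))


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    consistency: float   # two-way mixed, average measures, consistency
    agreement: float     # two-way, average measures, absolute agreement
    ms_between: float
    ms_sessions: float
    ms_error: float


def icc_3k(data: np.ndarray) -> ICCResult:
    """Average-measures intraclass correlation from a subjects × sessions matrix.

    Computes the two-way ANOVA mean squares (between subjects, between
    sessions, residual) and from them both average-measures forms:
    consistency ``(MS_B − MS_E)/MS_B`` and absolute agreement
    ``(MS_B − MS_E)/(MS_B + (MS_S − MS_E)/n)``.  Reports default to the
    absolute-agreement form.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise DomainError("data must be a 2-D subjects x sessions matrix")
    n, k = X.shape
    if n < 3 or k < 2:
        raise DomainError("need at least 3 subjects and 2 sessions")
    if not np.all(np.isfinite(X)):
        raise DomainError("ICC requires a complete, finite matrix")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_between = k * np.sum((row_means - grand) ** 2)
    ss_sessions = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_error = ss_total - ss_between - ss_sessions
    ms_b = ss_between / (n - 1)
    ms_s = ss_sessions / (k - 1)
    ms_e = ss_error / ((n - 1) * (k - 1))
    if ms_b == 0:
        raise UndefinedStatisticError("zero between-subject variance: ICC undefined")
    consistency = (ms_b - ms_e) / ms_b
    agreement = (ms_b - ms_e) / (ms_b + (ms_s - ms_e) / n)
    return ICCResult(consistency=float(consistency), agreement=float(agreement),
                     ms_between=float(ms_b), ms_sessions=float(ms_s), ms_error=float(ms_e))


# ---------------------------------------------------------------------------
# Test-retest waveform reliability
# ---------------------------------------------------------------------------

def intersession_waveform_reliability(session1: np.ndarray, session2: np.ndarray) -> tuple[float, bool, float]:
    """Between-session CMC and RMSE for one channel.

    ``session1``/``session2`` are (n_trials, F) stacks of matched, time-
    normalized waveforms from the two sessions.  The two sessions act as the
    P = 2 protocols of the CMC; the RMSE compares the session-mean
    waveforms.  Returns ``(cmc, complex_flag, rmse)``.
    """
    s1 = np.atleast_2d(np.asarray(session1, dtype=float))
    s2 = np.atleast_2d(np.asarray(session2, dtype=float))
    if s1.shape != s2.shape:
        raise PairingError("sessions must contain the same number of matched trials/frames")
    stacked = np.stack([s1, s2], axis=1)  # (G, P=2, F)
    value, flag = cmc(stacked)
    return value, flag, rmse(s1.mean(axis=0), s2.mean(axis=0))
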