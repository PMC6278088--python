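"""Evaluation metrics: CNR, channel-improvement fraction, correlation, robust t.

The contrast-to-noise ratio of a trial is

    CNR = (mean(task) - mean(rest)) / sqrt(var(task) + var(rest))

with the task window 4-14 s after the trial onset and the rest window the
6 s immediately preceding it (both half-open, converted to sample indices
by floor), averaged over retained trials.  Robust t-values against the
expected HR use iteratively reweighted least squares with the Tukey
bisquare weight (tuning constant 4.685) and MAD scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "CNRReport",
    "cnr",
    "improvement_fraction",
    "tvalue_vs_expected",
    "pearson",
]


@dataclass(frozen=True)
class CNRReport:
    """Per-trial CNRs with their mean and bookkeeping flags."""

    per_trial: np.ndarray
    value: float
    skipped_trials: tuple[int, ...] = ()
    undefined_trials: tuple[int, ...] = ()
    task_window: tuple[float, float] = (4.0, 14.0)
    rest_window: tuple[float, float] = (-6.0, 0.0)


def _window_slice(onset_s: float, window: tuple[float, float], fs: float, n: int):
    start = int(np.floor((onset_s + window[0]) * fs))
    stop = int(np.floor((onset_s + window[1]) * fs))
    if start < 0 or stop > n or stop <= start + 1:
        return None
    return slice(start, stop)


def cnr(
    series: np.ndarray,
    onsets: Sequence[float],
    fs: float,
    task_window: tuple[float, float] = (4.0, 14.0),
    rest_window: tuple[float, float] = (-6.0, 0.0),
) -> CNRReport:
    """Per-trial contrast-to-noise ratio, averaged over retained trials.

    Trials whose windows fall outside the recording are skipped and
    reported in ``skipped_trials``; a trial with zero variance in both
    windows yields NaN and is listed in ``undefined_trials`` (excluded
    from the mean).
    """
    y = np.asarray(series, dtype=float)
    if task_window[0] < rest_window[1] and rest_window[0] < task_window[1]:
        raise ValueError("task and rest windows must not overlap")
    values: list[float] = []
    skipped: list[int] = []
    undefined: list[int] = []
    for i, onset in enumerate(onsets):
        ts = _window_slice(onset, task_window, fs, y.size)
        rs = _window_slice(onset, rest_window, fs, y.size)
        if ts is None or rs is None:
            skipped.append(i)
            values.append(np.nan)
            continue
        task = y[ts]
        rest = y[rs]
        denom = task.var(ddof=1) + rest.var(ddof=1)
        if denom == 0:
            undefined.append(i)
            values.append(np.nan)
            continue
        values.append((task.mean() - rest.mean()) / np.sqrt(denom))
    arr = np.asarray(values)
    finite = arr[np.isfinite(arr)]
    mean = float(finite.mean()) if finite.size else float("nan")
    return CNRReport(
        per_trial=arr,
        value=mean,
        skipped_trials=tuple(skipped),
        undefined_trials=tuple(undefined),
        task_window=task_window,
        rest_window=rest_window,
    )


def improvement_fraction(
    cnr_a: Mapping[str, float], cnr_b: Mapping[str, float]
) -> float:
    """Percentage of channels where method a's CNR strictly exceeds b's.

    Ties count as not improved.  Inputs map channel id to (aggregate) CNR;
    the key sets must match.
    """
    if not cnr_a:
        raise ValueError("empty channel set")
    if set(cnr_a) != set(cnr_b):
        raise ValueError("channel sets differ")
    improved = sum(1 for ch in cnr_a if cnr_a[ch] > cnr_b[ch])
    return 100.0 * improved / len(cnr_a)


def tvalue_vs_expected(
    measured_hr: np.ndarray, expected_hr: np.ndarray
) -> float:
    """Robust-regression t statistic of the measured HR on the expected HR.

    IRLS with Tukey bisquare weights (c = 4.685) and MAD scale, regressing
    measured on [1, expected]; returns slope / SE(slope).  A numerically
    perfect fit (zero residual scale) returns +/-inf with the slope's sign.
    """
    y = np.asarray(measured_hr, dtype=float)
    x = np.asarray(expected_hr, dtype=float)
    if y.size != x.size:
        raise ValueError("series must have equal length")
    if y.size < 10:
        raise ValueError("need at least 10 samples")
    if x.std() == 0:
        raise ValueError("expected HR has zero variance")
    design = sm.add_constant(x)
    # detect an (affinely) exact fit first: IRLS scale would be zero
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ref = max(np.abs(y).max(), 1.0)
    if np.abs(resid).max() < 1e-12 * ref:
        return float(np.copysign(np.inf, slope))
    model = sm.RLM(y, design, M=sm.robust.norms.TukeyBiweight(c=4.685))
    fit = model.fit(scale_est="mad")
    return float(fit.params[1] / fit.bse[1])


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation with validation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    return float(stats.pearsonr(a, b).statistic)
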