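"""Expected hemodynamic response and basis construction.

The expected HR ``u(t)`` drives the adaptive filter: together with its
first and second finite-difference derivatives it spans the task-locked
subspace of the regression model.  The default generator convolves the
stimulus boxcar with the canonical double-gamma impulse response (peak at
6 s, undershoot at 16 s, undershoot ratio 1/6); the kernel is pluggable so
a subject-specific impulse response can be substituted.  A Gaussian bump
basis used by the Kalman-filter comparator lives here as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import gamma as _gamma


@dataclass(frozen=True)
class StimulusTrain:
    """Trial onsets/durations (seconds) with per-trial condition labels."""

    onsets: np.ndarray
    durations: np.ndarray
    conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        if onsets.shape != durations.shape:
            raise ValueError("onsets and durations must have equal length")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(durations <= 0):
            raise ValueError("durations must be positive")
        if self.conditions and len(self.conditions) != onsets.size:
            raise ValueError("conditions must match the number of events")

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)


@dataclass(frozen=True)
class ExpectedHR:
    """Expected HR ``u`` with finite-difference derivatives ``du``, ``d2u``."""

    u: np.ndarray
    du: np.ndarray
    d2u: np.ndarray
    fs: float
    generator: str = "double-gamma"


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical impulse response: difference of two gamma densities.

    Shape parameters equal the peak/undershoot delays (unit scale), so the
    positive lobe peaks near ``peak_s`` and the undershoot near
    ``undershoot_s``.  The kernel is scaled to a positive peak of 1.
    """
    t = np.asarray(t, dtype=float)
    h = _gamma.pdf(t, peak_s, scale=1.0) - ratio * _gamma.pdf(t, undershoot_s, scale=1.0)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def expected_hr(
    stim: StimulusTrain,
    fs: float,
    n_samples: int,
    hrf_params: dict | None = None,
    kernel: Callable[[np.ndarray], np.ndarray] | None = None,
    kernel_support_s: float = 32.0,
) -> ExpectedHR:
    """Generate the expected HR from a stimulus train.

    ``u`` is the stimulus boxcar convolved with the impulse-response kernel
    (Riemann sum, dt = 1/fs) truncated to ``n_samples``; it is zero before
    the first onset.  Derivatives come from :func:`derivatives`.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_samples < 3:
        raise ValueError("n_samples must be at least 3")
    t = np.arange(n_samples) / fs
    duration = n_samples / fs
    for onset, dur in zip(stim.onsets, stim.durations):
        if onset + dur > duration + 0.5 / fs:
            raise ValueError(
                f"event at onset {onset:g}s with duration {dur:g}s extends past "
                f"the {duration:g}s recording"
            )
    box = np.zeros(n_samples)
    for onset, dur in zip(stim.onsets, stim.durations):
        mask = (t >= onset) & (t < onset + dur)
        if not mask.any():  # sub-sample event: mark the onset sample
            mask[min(int(round(onset * fs)), n_samples - 1)] = True
        box[mask] = 1.0
    if kernel is None:
        params = dict(hrf_params or {})
        kern_fn = lambda tt: double_gamma_hrf(tt, **params)  # noqa: E731
    else:
        kern_fn = kernel
    tk = np.arange(0.0, kernel_support_s, 1.0 / fs)
    k = kern_fn(tk)
    u = np.convolve(box, k)[:n_samples] / fs
    du, d2u = derivatives(u, fs)
    return ExpectedHR(u=u, du=du, d2u=d2u, fs=fs)


def derivatives(u: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Central finite differences of ``u`` scaled by ``fs`` and ``fs**2``.

    Interior samples use the symmetric stencils ``(u[i+1]-u[i-1])/2 * fs``
    and ``(u[i+1]-2u[i]+u[i-1]) * fs**2``; boundaries fall back to one-sided
    differences of the same order where possible.
    """
    u = np.asarray(u, dtype=float)
    if u.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    du = np.empty_like(u)
    du[1:-1] = (u[2:] - u[:-2]) * (fs / 2.0)
    du[0] = (u[1] - u[0]) * fs
    du[-1] = (u[-1] - u[-2]) * fs
    d2u = np.empty_like(u)
    d2u[1:-1] = (u[2:] - 2.0 * u[1:-1] + u[:-2]) * fs * fs
    d2u[0] = d2u[1]
    d2u[-1] = d2u[-2]
    return du, d2u


def gaussian_basis(
    duration_s: float = 30.0,
    fs: float = 1.81,
    n: int = 15,
    width: float | None = None,
) -> np.ndarray:
    """Gaussian bump basis over the modeled response window.

    ``n`` bumps with centers evenly spaced on ``[0, duration_s]`` and a
    common width (default spacing/1.5); each column is max-normalized to 1.
    Returns an array of shape ``(n_samples, n)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    t = np.arange(0.0, duration_s, 1.0 / fs)
    if n == 1:
        centers = np.array([duration_s / 2.0])
        spacing = duration_s / 2.0
    else:
        centers = np.linspace(0.0, duration_s, n)
        spacing = centers[1] - centers[0]
    w = spacing / 1.5 if width is None else float(width)
    if w <= 0:
        raise ValueError("width must be positive")
    cols = np.exp(-((t[:, None] - centers[None, :]) ** 2) / (2.0 * w * w))
    cols /= cols.max(axis=0, keepdims=True)
    return cols


def block_paradigm_train(
    initial_rest_s: float = 20.0,
    n_trials: int = 10,
    task_s: float = 10.0,
    rest_s: float = 20.0,
    conditions: Sequence[str] | None = None,
) -> StimulusTrain:
    """Stimulus train for a block paradigm (initial rest, then task/rest trials)."""
    onsets = initial_rest_s + (task_s + rest_s) * np.arange(n_trials)
    durations = np.full(n_trials, task_s)
    if conditions is None:
        conditions = tuple("task" for _ in range(n_trials))
    return StimulusTrain(onsets=onsets, durations=durations, conditions=tuple(conditions))
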