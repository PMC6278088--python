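"""Baseline drift removal and frequency-domain comparison filters.

Slow instrumental/physiological drift is removed by subtracting a
least-squares polynomial fit (default degree 4).  The low-pass and
band-pass comparators are zero-phase 4th-order Butterworth filters
(forward-backward application), the field's de-facto default; zero-phase
filtering avoids latency distortion of trial averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class FilterSpec:
    """Digital filter specification for :func:`apply_filter`."""

    kind: str  # "lowpass" | "bandpass"
    cutoffs: tuple[float, ...]
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass"):
            raise ValueError("kind must be 'lowpass' or 'bandpass'")
        n_expected = 1 if self.kind == "lowpass" else 2
        if len(self.cutoffs) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} cutoff(s)")
        if any(c <= 0 for c in self.cutoffs):
            raise ValueError("cutoffs must be positive")
        if self.kind == "bandpass" and self.cutoffs[0] >= self.cutoffs[1]:
            raise ValueError("bandpass cutoffs must be ordered low < high")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def validate_for(self, fs: float) -> None:
        nyq = 0.5 * fs
        for c in self.cutoffs:
            if c >= nyq:
                raise ValueError(f"cutoff {c:g} Hz at or above Nyquist {nyq:g} Hz")

    def sos(self, fs: float) -> np.ndarray:
        self.validate_for(fs)
        wn = self.cutoffs[0] if self.kind == "lowpass" else list(self.cutoffs)
        return signal.butter(self.order, wn, btype=self.kind, fs=fs, output="sos")


def detrend_poly(series: np.ndarray, order: int = 4) -> np.ndarray:
    """Subtract the least-squares polynomial fit of the given degree.

    The residual is orthogonal to the polynomial basis, hence the
    operation is idempotent.  The abscissa is standardized internally for
    numerical conditioning.
    """
    y = np.asarray(series, dtype=float)
    if order < 0:
        raise ValueError("order must be non-negative")
    if order >= y.size - 1:
        raise ValueError(f"order {order} too high for series of length {y.size}")
    x = np.arange(y.size, dtype=float)
    x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    design = np.vander(x, order + 1)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def apply_filter(series: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply the specified Butterworth filter (zero-phase by default)."""
    y = np.asarray(series, dtype=float)
    sos = spec.sos(fs)
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, y)
    return signal.sosfilt(sos, y)


def filter_gain(spec: FilterSpec, fs: float, freq_hz: float) -> float:
    """Analytic amplitude gain at ``freq_hz`` (squared magnitude if zero-phase)."""
    sos = spec.sos(fs)
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    g = np.abs(h[0])
    return float(g * g) if spec.zero_phase else float(g)
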