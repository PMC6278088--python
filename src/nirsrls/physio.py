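"""Physiological-noise frequency estimation from resting-state data.

Cardiac (~1 Hz), respiratory (~0.25 Hz) and Mayer-wave (~0.1 Hz)
oscillations contaminate fNIRS channels.  Their per-experiment frequencies
are estimated from the initial resting segment by FFT peak picking within
three ordered search bands; a fixed-frequency mode is kept for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: nominal physiological frequencies (Mayer, respiratory, cardiac), Hz
FIXED_FREQUENCIES: tuple[float, float, float] = (0.1, 0.25, 1.0)


@dataclass(frozen=True)
class SearchBands:
    """Hz intervals bracketing the three physiological oscillations.

    Defaults bracket the nominal 0.1/0.25/1 Hz rhythms while respecting the
    Nyquist limit of slow fNIRS sampling: at fs = 1.81 Hz the cardiac band
    is clipped below 0.905 Hz, so heart rate is resolved near 0.8-0.9 Hz.
    """

    mayer: tuple[float, float] = (0.05, 0.2)
    respiratory: tuple[float, float] = (0.2, 0.5)
    cardiac: tuple[float, float] = (0.5, 1.5)

    def clipped(self, fs: float) -> "SearchBands":
        """Clip band upper edges just below the Nyquist frequency."""
        nyq = 0.5 * fs * (1.0 - 1e-9)
        bands = []
        for lo, hi in (self.mayer, self.respiratory, self.cardiac):
            bands.append((lo, min(hi, nyq)))
        out = SearchBands(*bands)
        out.validate()
        return out

    def validate(self) -> None:
        seq = [self.mayer, self.respiratory, self.cardiac]
        for lo, hi in seq:
            if not 0 < lo < hi:
                raise ValueError(f"invalid band ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(seq, seq[1:]):
            if lo2 < hi:
                raise ValueError("bands must be ordered and non-overlapping")


@dataclass(frozen=True)
class PhysioFrequencies:
    """Mayer/respiratory/cardiac frequencies with estimation metadata."""

    f_mayer: float
    f_resp: float
    f_cardiac: float
    mode: str = "estimated"  # "estimated" | "fixed"
    fallback: tuple[bool, bool, bool] = (False, False, False)
    bin_width_hz: float = float("nan")

    @property
    def frequencies(self) -> tuple[float, float, float]:
        return (self.f_mayer, self.f_resp, self.f_cardiac)


def fixed_frequencies(fs: float) -> PhysioFrequencies:
    """The nominal 0.1/0.25/1 Hz set, clipped below Nyquist.

    Clipping stops at 98% of fs/2: a sinusoid sampled exactly at the
    Nyquist frequency with phase 0 is identically zero and would leave its
    coefficient unidentifiable.
    """
    nyq = 0.5 * fs * 0.98
    fm, fr, fc = (min(f, nyq) for f in FIXED_FREQUENCIES)
    return PhysioFrequencies(fm, fr, fc, mode="fixed")


def estimate_frequencies(
    rest_segment: np.ndarray,
    fs: float,
    bands: SearchBands | None = None,
    min_duration_s: float = 20.0,
    peak_floor_ratio: float = 5.0,
) -> PhysioFrequencies:
    """FFT-peak frequency estimation on a resting-state segment.

    The mean-removed segment is zero-padded to the next power of two at or
    above 8x its length and transformed; within each search band the
    frequency of the maximum DFT magnitude is returned.  Resolution is
    ``fs / n_fft``.  A band whose peak does not exceed ``peak_floor_ratio``
    times the median spectral magnitude (or that is empty after Nyquist
    clipping) falls back to the nominal fixed value with its flag set.
    """
    x = np.asarray(rest_segment, dtype=float)
    if x.ndim != 1:
        raise ValueError("rest_segment must be one-dimensional")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n_min = int(np.floor(min_duration_s * fs))
    if x.size < n_min:
        raise ValueError(
            f"rest segment has {x.size} samples; need at least {n_min} "
            f"({min_duration_s:g} s at {fs:g} Hz)"
        )
    bands = (bands or SearchBands()).clipped(fs)

    n_fft = 1 << int(np.ceil(np.log2(8 * x.size)))
    mag = np.abs(np.fft.rfft(x - x.mean(), n_fft))
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    floor = np.median(mag[1:])  # exclude the (zeroed) DC bin

    fallback_vals = fixed_frequencies(fs)
    out: list[float] = []
    flags: list[bool] = []
    for (lo, hi), fb in zip(
        (bands.mayer, bands.respiratory, bands.cardiac), fallback_vals.frequencies
    ):
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            out.append(fb)
            flags.append(True)
            continue
        idx = int(np.argmax(mag[sel]))
        peak = mag[sel][idx]
        if floor > 0 and peak < peak_floor_ratio * floor:
            out.append(fb)
            flags.append(True)
        else:
            out.append(float(freqs[sel][idx]))
            flags.append(False)
    return PhysioFrequencies(
        out[0],
        out[1],
        out[2],
        mode="estimated",
        fallback=tuple(flags),
        bin_width_hz=fs / n_fft,
    )
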