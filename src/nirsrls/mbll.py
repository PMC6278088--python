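"""Modified Beer-Lambert law conversion for dual-wavelength CW-fNIRS.

Detected light intensities at two wavelengths (defaults 760 and 830 nm)
are converted to optical-density changes relative to a baseline window,
then to oxy-/deoxy-hemoglobin concentration changes by inverting the 2x2
extinction system

    dOD_lambda = d * DPF_lambda * (eps_HbO,lambda * dHbO + eps_HbR,lambda * dHbR)

with d the emitter-detector distance (cm) and DPF the differential
pathlength factor.  Optical density uses log base 10, the dominant fNIRS
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: molar extinction coefficients, 1/(mM cm), keyed by (chromophore, nm).
#: Values follow the compiled Gratzer/Cope hemoglobin spectra widely used
#: in fNIRS processing software.
DEFAULT_EXTINCTION: dict[tuple[str, int], float] = {
    ("HbO", 760): 1.4866,
    ("HbR", 760): 3.8437,
    ("HbO", 830): 2.3216,
    ("HbR", 830): 1.7917,
}

#: default differential pathlength factor (dimensionless), both wavelengths
DEFAULT_DPF: float = 6.0


@dataclass(frozen=True)
class IntensitySeries:
    """Per-wavelength detected intensities with a baseline window."""

    intensities: dict[int, np.ndarray]  # wavelength nm -> series
    baseline: tuple[int, int] = (0, 36)  # sample range [start, stop)

    def __post_init__(self) -> None:
        if len(self.intensities) != 2:
            raise ValueError("exactly two wavelengths are required")
        start, stop = self.baseline
        if stop <= start:
            raise ValueError("baseline window must be non-empty")
        for wl, series in self.intensities.items():
            series = np.asarray(series, dtype=float)
            bad = np.flatnonzero(series <= 0)
            if bad.size:
                raise ValueError(
                    f"non-positive intensity at wavelength {wl} nm, sample {bad[0]}"
                )


@dataclass(frozen=True)
class MbllParams:
    """Extinction coefficients, pathlength factors and geometry."""

    distance_cm: float = 3.0
    dpf: dict[int, float] = field(default_factory=lambda: {760: DEFAULT_DPF, 830: DEFAULT_DPF})
    extinction: dict[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION)
    )
    wavelengths: tuple[int, int] = (760, 830)

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise ValueError("distance must be positive")
        for wl in self.wavelengths:
            if self.dpf.get(wl, 0) <= 0:
                raise ValueError(f"DPF for {wl} nm must be positive")

    def pathlength_matrix(self) -> np.ndarray:
        """Rows = wavelengths, columns = (HbO, HbR); includes d * DPF."""
        rows = []
        for wl in self.wavelengths:
            rows.append(
                [
                    self.distance_cm * self.dpf[wl] * self.extinction[("HbO", wl)],
                    self.distance_cm * self.dpf[wl] * self.extinction[("HbR", wl)],
                ]
            )
        mat = np.asarray(rows, dtype=float)
        if np.linalg.cond(mat) > 1e8:
            raise ValueError(
                "extinction system is singular or ill-conditioned "
                f"(condition number {np.linalg.cond(mat):.3g})"
            )
        return mat


def intensity_to_od(series: IntensitySeries) -> dict[int, np.ndarray]:
    """Optical-density change dOD(t) = -log10(I(t) / I0) per wavelength.

    ``I0`` is the mean intensity over the baseline window, so the mean of
    dOD over that window is ~0.
    """
    start, stop = series.baseline
    out: dict[int, np.ndarray] = {}
    for wl, values in series.intensities.items():
        values = np.asarray(values, dtype=float)
        if stop > values.size:
            raise ValueError("baseline window extends past the series")
        i0 = values[start:stop].mean()
        out[wl] = -np.log10(values / i0)
    return out


def od_to_hb(
    od_first: np.ndarray,
    od_second: np.ndarray,
    params: MbllParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the MBLL system per sample, returning (dHbO, dHbR) in mM.

    The two OD series must be ordered like ``params.wavelengths``.
    """
    params = params or MbllParams()
    od_first = np.asarray(od_first, dtype=float)
    od_second = np.asarray(od_second, dtype=float)
    if od_first.shape != od_second.shape:
        raise ValueError("OD series must have equal length")
    mat = params.pathlength_matrix()
    inv = np.linalg.inv(mat)
    stacked = np.vstack([od_first, od_second])  # (2, n)
    hb = inv @ stacked
    return hb[0], hb[1]


def hb_to_od(
    dhbo: np.ndarray, dhbr: np.ndarray, params: MbllParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Forward MBLL map, the exact inverse of :func:`od_to_hb`."""
    params = params or MbllParams()
    mat = params.pathlength_matrix()
    stacked = np.vstack([np.asarray(dhbo, float), np.asarray(dhbr, float)])
    od = mat @ stacked
    return od[0], od[1]
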