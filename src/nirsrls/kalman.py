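"""Kalman-filter comparator: Gaussian HR basis plus SS regressor.

The comparison model expresses a long channel as a trial-locked linear
combination of 15 Gaussian bumps (the canonical-HR basis) plus a scaled
short-separation measurement.  The weights evolve as a random walk
x_{t+1} = x_t + w, w ~ N(0, Q), observed through y_t = m_t^T x_t + v with
m_t the basis row at the time since the latest trial onset concatenated
with y_ss(t).  Defaults follow the published comparison configuration:
initial state covariance diag 1e-1 and process noise diag 5e-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hrf import StimulusTrain, gaussian_basis


@dataclass(frozen=True)
class KalmanConfig:
    """State-space configuration for the comparator."""

    n_basis: int = 15
    basis_window_s: float = 30.0
    basis_width_s: float | None = None
    initial_cov: float = 1e-1
    process_noise: float = 5e-4
    measurement_noise: float = 1e-3

    def __post_init__(self) -> None:
        if self.initial_cov <= 0 or self.measurement_noise <= 0:
            raise ValueError("initial and measurement covariances must be positive")
        if self.process_noise < 0:
            raise ValueError("process noise must be non-negative")
        if self.n_basis < 1:
            raise ValueError("need at least one basis function")


def _basis_rows(
    stim: StimulusTrain, fs: float, n_samples: int, cfg: KalmanConfig
) -> np.ndarray:
    """Trial-locked basis rows: restart the Gaussian basis at each onset."""
    basis = gaussian_basis(cfg.basis_window_s, fs, cfg.n_basis, cfg.basis_width_s)
    rows = np.zeros((n_samples, cfg.n_basis))
    onsets = np.asarray(stim.onsets, dtype=float)
    t = np.arange(n_samples) / fs
    for i, ti in enumerate(t):
        past = onsets[onsets <= ti]
        if past.size == 0:
            continue
        tau = ti - past[-1]
        j = int(round(tau * fs))
        if 0 <= j < basis.shape[0]:
            rows[i] = basis[j]
    return rows


def kalman_denoise(
    y_long: np.ndarray,
    y_ss: np.ndarray,
    stim: StimulusTrain,
    fs: float,
    cfg: KalmanConfig | None = None,
    return_state: bool = False,
):
    """Estimate the HR by Kalman filtering of the basis + SS model.

    Returns the estimated HR series (basis rows times final basis
    weights); with ``return_state=True`` also the final state vector and
    covariance.
    """
    cfg = cfg or KalmanConfig()
    y = np.asarray(y_long, dtype=float)
    ss = np.asarray(y_ss, dtype=float)
    if y.shape != ss.shape:
        raise ValueError("y_long and y_ss must have equal length")
    n = y.size
    rows = _basis_rows(stim, fs, n, cfg)
    M = np.hstack([rows, ss[:, None]])  # (n, n_basis + 1) observation rows

    dim = cfg.n_basis + 1
    x = np.zeros(dim)
    P = np.eye(dim) * cfg.initial_cov
    Q = np.eye(dim) * cfg.process_noise
    R = cfg.measurement_noise
    for i in range(n):
        # predict (identity transition)
        P = P + Q
        m = M[i]
        s = m @ P @ m + R
        if s <= 0:
            raise ValueError("innovation covariance must be positive")
        k = (P @ m) / s
        x = x + k * (y[i] - m @ x)
        P = P - np.outer(k, m @ P)
        P = 0.5 * (P + P.T)
    hr = rows @ x[: cfg.n_basis]
    if return_state:
        return hr, x, P
    return hr
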