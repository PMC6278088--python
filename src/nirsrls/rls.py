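"""Recursive least squares with exponential forgetting: the filter core.

A long-separation fNIRS channel is modeled per sample as

    y(t) = a1*u(t) + a2*du(t) + a3*d2u(t) + a4*y_ss(t)
           + sum_m b_m*sin(2*pi*f_m*t) + b0 + eps(t)

with u the expected HR, du/d2u its derivatives, y_ss the short-separation
nuisance channel, q sinusoids at the physiological frequencies and a
constant baseline term.  The coefficient vector is tracked online by
exponentially weighted recursive least squares: minimizing
sum_k lambda**(t-k) * (y(k) - phi(k)^T beta)**2 yields the update

    k(t)   = P phi / (lambda + phi^T P phi)
    beta  <- beta + k(t) * (y - phi^T beta)
    P     <- (P - k(t) phi^T P) / lambda

The denoised HR is the task-locked part a1*u + a2*du + a3*d2u evaluated
with the instantaneous coefficient trajectory (a converged-coefficient
mode is available for offline use).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hrf import ExpectedHR
from .physio import PhysioFrequencies

__all__ = [
    "RLSInit",
    "RLSEState",
    "FilterResult",
    "build_regressor",
    "rlse_update",
    "run_filter",
    "run_filter_no_ss",
    "batch_ols",
]


@dataclass(frozen=True)
class RLSInit:
    """Initial coefficient vector and covariance for the recursion.

    ``delta`` scales the default uninformative prior P(0) = delta * I;
    explicit ``beta0``/``P0`` arrays override it.
    """

    delta: float = 1e6
    beta0: np.ndarray | None = None
    P0: np.ndarray | None = None


@dataclass
class RLSEState:
    """Per-sample estimator state: coefficients, covariance, forgetting."""

    beta: np.ndarray
    P: np.ndarray
    lam: float
    t: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("forgetting factor must lie in (0, 1]")
        p = self.beta.size
        if self.P.shape != (p, p):
            raise ValueError("covariance shape does not match coefficient vector")
        if not np.allclose(self.P, self.P.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")


@dataclass(frozen=True)
class FilterResult:
    """Output of a filtering run.

    ``components`` maps each regressor name to its per-sample contribution
    (coefficient trajectory times regressor column); their sum equals
    ``fitted`` exactly and ``residual = y - fitted``.  ``extracted_hr`` is
    the sum of the u/du/d2u components.
    """

    fitted: np.ndarray
    extracted_hr: np.ndarray
    components: dict[str, np.ndarray]
    residual: np.ndarray
    coefficients: np.ndarray  # (n_samples, p) trajectory
    regressor_names: tuple[str, ...]
    freqs: PhysioFrequencies
    lam: float

    @property
    def final_coefficients(self) -> np.ndarray:
        return self.coefficients[-1]


def build_regressor(
    exp_hr: ExpectedHR,
    y_ss_value: float | None,
    freqs: PhysioFrequencies,
    t_index: int,
    fs: float,
    with_cosines: bool = False,
) -> np.ndarray:
    """Regression vector phi(t) for one sample.

    Order: [u, du, d2u, (y_ss,) sin(2*pi*f_m*t)..., (cos(...)...,) 1] with
    t = t_index / fs seconds.  Pass ``y_ss_value=None`` to omit the SS
    entry (the no-SS model variant).
    """
    n = exp_hr.u.size
    if not 0 <= t_index < n:
        raise IndexError(f"t_index {t_index} outside series of length {n}")
    t = t_index / fs
    entries = [exp_hr.u[t_index], exp_hr.du[t_index], exp_hr.d2u[t_index]]
    if y_ss_value is not None:
        if not np.isfinite(y_ss_value):
            raise ValueError(f"non-finite SS value at sample {t_index}")
        entries.append(float(y_ss_value))
    for f in freqs.frequencies:
        entries.append(np.sin(2.0 * np.pi * f * t))
    if with_cosines:
        for f in freqs.frequencies:
            entries.append(np.cos(2.0 * np.pi * f * t))
    entries.append(1.0)
    return np.asarray(entries, dtype=float)


def regressor_names(with_ss: bool, with_cosines: bool = False) -> tuple[str, ...]:
    names = ["u", "du", "d2u"]
    if with_ss:
        names.append("ss")
    names += ["sin_mayer", "sin_resp", "sin_cardiac"]
    if with_cosines:
        names += ["cos_mayer", "cos_resp", "cos_cardiac"]
    names.append("baseline")
    return tuple(names)


def rlse_update(state: RLSEState, phi: np.ndarray, y_observed: float) -> RLSEState:
    """One exponentially weighted RLS step; pure function of its inputs."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != state.beta.shape:
        raise ValueError("regressor dimension does not match state")
    if not np.all(np.isfinite(phi)) or not np.isfinite(y_observed):
        raise ValueError("non-finite input to rlse_update")
    P_phi = state.P @ phi
    denom = state.lam + phi @ P_phi
    assert denom > 0.0, "gain denominator must be positive for PD covariance"
    gain = P_phi / denom
    innovation = y_observed - phi @ state.beta
    beta = state.beta + gain * innovation
    P = (state.P - np.outer(gain, P_phi)) / state.lam
    P = 0.5 * (P + P.T)
    return RLSEState(beta=beta, P=P, lam=state.lam, t=state.t + 1)


def _run(
    y: np.ndarray,
    Phi: np.ndarray,
    names: tuple[str, ...],
    lam: float,
    init: RLSInit,
    freqs: PhysioFrequencies,
    coefficient_mode: str,
) -> FilterResult:
    n, p = Phi.shape
    beta0 = np.zeros(p) if init.beta0 is None else np.asarray(init.beta0, dtype=float)
    P0 = init.delta * np.eye(p) if init.P0 is None else np.asarray(init.P0, dtype=float)
    state = RLSEState(beta=beta0.copy(), P=P0.copy(), lam=lam)
    traj = np.empty((n, p))
    for i in range(n):
        state = rlse_update(state, Phi[i], y[i])
        traj[i] = state.beta
    if coefficient_mode == "final":
        coeffs = np.broadcast_to(traj[-1], (n, p)).copy()
    elif coefficient_mode == "instantaneous":
        coeffs = traj
    else:
        raise ValueError("coefficient_mode must be 'instantaneous' or 'final'")
    contrib = coeffs * Phi
    components = {name: contrib[:, j].copy() for j, name in enumerate(names)}
    # accumulate in component order so the additivity invariant holds exactly
    fitted = np.zeros(n)
    for j in range(p):
        fitted = fitted + contrib[:, j]
    hr_cols = [names.index("u"), names.index("du"), names.index("d2u")]
    extracted = contrib[:, hr_cols].sum(axis=1)
    return FilterResult(
        fitted=fitted,
        extracted_hr=extracted,
        components=components,
        residual=y - fitted,
        coefficients=traj,
        regressor_names=names,
        freqs=freqs,
        lam=lam,
    )


def _validate_series(y: np.ndarray, name: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        raise ValueError(f"{name} contains a non-finite value at sample {bad[0]}")
    return y


def run_filter(
    y_long: np.ndarray,
    y_ss: np.ndarray,
    exp_hr: ExpectedHR,
    freqs: PhysioFrequencies,
    lam: float = 0.99,
    init: RLSInit | None = None,
    with_cosines: bool = False,
    coefficient_mode: str = "instantaneous",
) -> FilterResult:
    """Filter one long channel with its short-separation regressor."""
    y = _validate_series(y_long, "y_long")
    ss = _validate_series(y_ss, "y_ss")
    if y.size != ss.size or y.size != exp_hr.u.size:
        raise ValueError("y_long, y_ss and expected HR must have equal length")
    init = init or RLSInit()
    names = regressor_names(with_ss=True, with_cosines=with_cosines)
    Phi = np.array(
        [
            build_regressor(exp_hr, ss[i], freqs, i, exp_hr.fs, with_cosines)
            for i in range(y.size)
        ]
    )
    return _run(y, Phi, names, lam, init, freqs, coefficient_mode)


def run_filter_no_ss(
    y_long: np.ndarray,
    exp_hr: ExpectedHR,
    freqs: PhysioFrequencies,
    lam: float = 0.99,
    init: RLSInit | None = None,
    with_cosines: bool = False,
    coefficient_mode: str = "instantaneous",
) -> FilterResult:
    """Filter variant omitting the short-separation regressor.

    Used for the fixed-vs-estimated frequency comparison and for single
    synthetic mixtures that have no superficial channel.
    """
    y = _validate_series(y_long, "y_long")
    if y.size != exp_hr.u.size:
        raise ValueError("y_long and expected HR must have equal length")
    init = init or RLSInit()
    names = regressor_names(with_ss=False, with_cosines=with_cosines)
    Phi = np.array(
        [
            build_regressor(exp_hr, None, freqs, i, exp_hr.fs, with_cosines)
            for i in range(y.size)
        ]
    )
    return _run(y, Phi, names, lam, init, freqs, coefficient_mode)


def batch_ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ordinary least squares on a full-column-rank design matrix."""
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if design.ndim != 2 or design.shape[0] != y.size:
        raise ValueError("design must be 2-D with one row per observation")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]})"
        )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef
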