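"""Synthetic fNIRS generators with known ground truth.

Two generators are provided.  :func:`make_oscillator_mixture` builds the
single-channel validation mixture — expected-HR waveform plus cardiac,
respiratory and Mayer sinusoids plus white Gaussian noise — used to verify
that the adaptive filter separates its components.
:func:`simulate_experiment` extends this to a multi-channel block-paradigm
experiment with short-separation channels, shared superficial noise,
polynomial drift and per-channel white noise, so the full pipeline is
testable without any recorded data.

Defaults emulate the slow-sampled motor-cortex protocol this package
targets: 20 s initial rest followed by ten trials of 10 s task + 20 s rest
(320 s total) sampled at 1.81 Hz, a 0.5 cm short-separation distance and
~3 cm long channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hrf import StimulusTrain, block_paradigm_train, expected_hr

__all__ = [
    "MixtureConfig",
    "Paradigm",
    "ExperimentConfig",
    "GroundTruth",
    "ChannelRecord",
    "validation_mixture_config",
    "make_oscillator_mixture",
    "simulate_experiment",
]


@dataclass(frozen=True)
class MixtureConfig:
    """Single-channel oscillator-mixture configuration.

    Amplitudes are in signal units (the decomposition is scale-free);
    frequencies must stay below the Nyquist limit fs/2.
    """

    duration_s: float = 320.0
    fs: float = 1.81
    amp_hr: float = 1.0
    amp_cardiac: float = 0.4
    amp_resp: float = 0.3
    amp_mayer: float = 0.5
    f_cardiac: float = 0.9
    f_resp: float = 0.26
    f_mayer: float = 0.13
    phase_cardiac: float = 0.0
    phase_resp: float = 0.0
    phase_mayer: float = 0.0
    noise_sd: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        nyq = 0.5 * self.fs
        for name, f in (
            ("f_cardiac", self.f_cardiac),
            ("f_resp", self.f_resp),
            ("f_mayer", self.f_mayer),
        ):
            if not 0 < f < nyq:
                raise ValueError(
                    f"{name}={f:g} Hz must lie strictly below the Nyquist "
                    f"frequency {nyq:g} Hz"
                )

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.duration_s * self.fs))


def validation_mixture_config(seed: int = 0) -> MixtureConfig:
    """Preset for the five-component validation mixture.

    Expected-HR block response at unit amplitude plus sinusoids at
    0.13 Hz (Mayer), 0.26 Hz (respiratory) and 0.9 Hz (cardiac) with
    amplitudes 0.5/0.3/0.4, and white noise of SD 1e-4, sampled at
    1.81 Hz for 320 s.
    """
    return MixtureConfig(seed=seed)


@dataclass(frozen=True)
class Paradigm:
    """Block paradigm: initial rest then ``n_trials`` of task + rest."""

    initial_rest_s: float = 20.0
    n_trials: int = 10
    task_s: float = 10.0
    rest_s: float = 20.0

    @property
    def total_s(self) -> float:
        return self.initial_rest_s + self.n_trials * (self.task_s + self.rest_s)

    def train(self) -> StimulusTrain:
        return block_paradigm_train(
            self.initial_rest_s, self.n_trials, self.task_s, self.rest_s
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Multi-channel experiment configuration.

    Each long channel mixes the task-locked HR, a gain times the shared
    superficial noise process, the physiological sinusoids, a degree-4
    polynomial drift and white noise; its paired short-separation channel
    sees the same superficial process and sinusoids but no HR.
    """

    paradigm: Paradigm = field(default_factory=Paradigm)
    fs: float = 1.81
    n_long: int = 40
    n_ss: int = 4
    hr_amplitude: float = 1.0
    superficial_gain: float = 0.6
    superficial_sd: float = 0.3
    amp_cardiac: float = 0.4
    amp_resp: float = 0.3
    amp_mayer: float = 0.5
    f_cardiac: float = 0.9
    f_resp: float = 0.26
    f_mayer: float = 0.13
    random_phases: bool = False
    drift_sd: float = 0.1
    noise_sd: float = 0.05
    long_distance_cm: float = 3.0
    ss_distance_cm: float = 0.5
    ss_map: dict | None = None  # long channel name -> SS channel name
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_long < 1 or self.n_ss < 1:
            raise ValueError("need at least one long and one SS channel")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        nyq = 0.5 * self.fs
        for f in (self.f_cardiac, self.f_resp, self.f_mayer):
            if not 0 < f < nyq:
                raise ValueError(f"frequency {f:g} Hz at or above Nyquist {nyq:g} Hz")

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.paradigm.total_s * self.fs))


@dataclass(frozen=True)
class GroundTruth:
    """Stored generator components; their sum equals the mixture exactly."""

    components: dict  # name -> array (single channel) or dict of arrays
    frequencies: tuple[float, float, float]  # (mayer, resp, cardiac), Hz
    coefficients: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ChannelRecord:
    """One optode pair's time series with geometry and role metadata."""

    channel_id: str
    values: np.ndarray
    fs: float
    distance_cm: float
    role: str  # "long" | "short"
    ss_partner: str | None = None
    emitter: int = 0
    detector: int = 0


def _expected_hr_component(paradigm: Paradigm, fs: float, n: int) -> np.ndarray:
    u = expected_hr(paradigm.train(), fs, n).u
    peak = np.max(np.abs(u))
    return u / peak if peak > 0 else u


def make_oscillator_mixture(
    config: MixtureConfig, paradigm: Paradigm | None = None
) -> tuple[dict[str, np.ndarray], np.ndarray, GroundTruth]:
    """Build the five-component validation mixture.

    Returns ``(components, mixture, truth)`` where ``components`` holds the
    expected-HR waveform (unit peak, scaled by ``amp_hr``), the three
    sinusoids and the noise realization, and ``mixture`` is their exact sum.
    """
    paradigm = paradigm or Paradigm()
    n = config.n_samples
    t = np.arange(n) / config.fs
    rng = np.random.default_rng(config.seed)
    hr = config.amp_hr * _expected_hr_component(paradigm, config.fs, n)
    components = {
        "hr": hr,
        "cardiac": config.amp_cardiac
        * np.sin(2 * np.pi * config.f_cardiac * t + config.phase_cardiac),
        "respiratory": config.amp_resp
        * np.sin(2 * np.pi * config.f_resp * t + config.phase_resp),
        "mayer": config.amp_mayer
        * np.sin(2 * np.pi * config.f_mayer * t + config.phase_mayer),
        "noise": rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n),
    }
    mixture = np.zeros(n)
    for comp in components.values():
        mixture = mixture + comp
    truth = GroundTruth(
        components=components,
        frequencies=(config.f_mayer, config.f_resp, config.f_cardiac),
    )
    return components, mixture, truth


def _superficial_process(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Slow shared scalp-hemodynamics surrogate: low-passed Gaussian noise."""
    from scipy.signal import butter, sosfiltfilt

    if sd == 0:
        return np.zeros(n)
    raw = rng.normal(0.0, 1.0, n)
    sos = butter(4, min(0.1, 0.45 * fs), btype="low", fs=fs, output="sos")
    x = sosfiltfilt(sos, raw)
    s = x.std()
    return x / s * sd if s > 0 else x


def simulate_experiment(
    config: ExperimentConfig,
) -> tuple[dict[str, ChannelRecord], StimulusTrain, GroundTruth]:
    """Simulate a multi-channel block-paradigm experiment.

    Long channels are named ``L01..`` and short-separation channels
    ``S01..``; long channel ``i`` is paired with SS channel ``i % n_ss``.
    All randomness flows from ``config.seed``.
    """
    n = config.n_samples
    fs = config.fs
    t = np.arange(n) / fs
    rng = np.random.default_rng(config.seed)
    stim = config.paradigm.train()
    hr_shape = _expected_hr_component(config.paradigm, fs, n)

    freqs = (config.f_mayer, config.f_resp, config.f_cardiac)
    amps = (config.amp_mayer, config.amp_resp, config.amp_cardiac)

    ss_names = [f"S{i + 1:02d}" for i in range(config.n_ss)]
    long_names = [f"L{i + 1:02d}" for i in range(config.n_long)]

    # one superficial process and one sinusoid phase set per SS group
    superficial = {}
    phases = {}
    for name in ss_names:
        superficial[name] = _superficial_process(rng, n, fs, config.superficial_sd)
        if config.random_phases:
            phases[name] = rng.uniform(0.0, 2.0 * np.pi, 3)
        else:
            phases[name] = np.zeros(3)

    def physio(name: str) -> np.ndarray:
        ph = phases[name]
        out = np.zeros(n)
        for a, f, p in zip(amps, freqs, ph):
            out = out + a * np.sin(2 * np.pi * f * t + p)
        return out

    records: dict[str, ChannelRecord] = {}
    comp_store: dict[str, dict[str, np.ndarray]] = {}

    for name in ss_names:
        comps = {
            "superficial": superficial[name],
            "physio": physio(name),
            "noise": rng.normal(0.0, config.noise_sd, n)
            if config.noise_sd > 0
            else np.zeros(n),
        }
        values = np.zeros(n)
        for c in comps.values():
            values = values + c
        comp_store[name] = comps
        records[name] = ChannelRecord(
            channel_id=name,
            values=values,
            fs=fs,
            distance_cm=config.ss_distance_cm,
            role="short",
        )

    tn = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)
    for i, name in enumerate(long_names):
        if config.ss_map is not None and name in config.ss_map:
            partner = config.ss_map[name]
            if partner not in ss_names:
                raise ValueError(
                    f"ss_map assigns {name} to unknown SS channel {partner!r}"
                )
        else:
            partner = ss_names[i % config.n_ss]
        drift_coef = rng.normal(0.0, config.drift_sd, 5)
        comps = {
            "hr": config.hr_amplitude * hr_shape,
            "superficial": config.superficial_gain * superficial[partner],
            "physio": physio(partner),
            "drift": np.polyval(drift_coef, tn),
            "noise": rng.normal(0.0, config.noise_sd, n)
            if config.noise_sd > 0
            else np.zeros(n),
        }
        values = np.zeros(n)
        for c in comps.values():
            values = values + c
        comp_store[name] = comps
        records[name] = ChannelRecord(
            channel_id=name,
            values=values,
            fs=fs,
            distance_cm=config.long_distance_cm,
            role="long",
            ss_partner=partner,
        )

    truth = GroundTruth(
        components=comp_store,
        frequencies=freqs,
        coefficients={"hr_amplitude": config.hr_amplitude,
                      "superficial_gain": config.superficial_gain},
    )
    return records, stim, truth
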