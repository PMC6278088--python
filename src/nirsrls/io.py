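"""Dataset readers/writers, run configuration and the end-to-end pipeline.

The native on-disk layout is deliberately plain text: a long-format data
CSV (time_s, channel_id, value), a channel-map CSV (channel_id, emitter,
detector, distance_cm, role, ss_partner) and a BIDS-style events TSV
(onset, duration, trial_type).  ``run_pipeline`` ties the stages together:
polynomial detrend, physiological-frequency estimation from the initial
rest, expected-HR generation, per-channel RLS filtering against the paired
short-separation channel, and CNR / correlation / robust-t metrics.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .hrf import StimulusTrain, expected_hr
from .metrics import cnr, improvement_fraction, pearson, tvalue_vs_expected
from .physio import SearchBands, estimate_frequencies, fixed_frequencies
from .preprocessing import detrend_poly
from .rls import RLSInit, run_filter, run_filter_no_ss
from .synthetic import ChannelRecord

__all__ = [
    "RunConfig",
    "write_dataset",
    "read_dataset",
    "run_pipeline",
]


class RunConfig(BaseModel):
    """Validated pipeline configuration; defaults match the target protocol."""

    fs: float = Field(default=1.81, gt=0)
    lam: float = Field(default=0.99, gt=0, le=1)
    freq_mode: str = "estimated"  # "estimated" | "fixed"
    rest_window_s: tuple[float, float] = (0.0, 20.0)
    detrend_order: int = Field(default=4, ge=0)
    lpf_cutoff_hz: float = Field(default=0.15, gt=0)
    task_window_s: tuple[float, float] = (4.0, 14.0)
    rest_cnr_window_s: tuple[float, float] = (-6.0, 0.0)
    with_cosines: bool = False
    use_ss: bool = True
    init_delta: float = Field(default=1e6, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.freq_mode not in ("estimated", "fixed"):
            raise ValueError("freq_mode must be 'estimated' or 'fixed'")
        if self.rest_window_s[1] <= self.rest_window_s[0]:
            raise ValueError("rest window must be non-empty")
        return self


def write_dataset(
    out_dir: str | Path,
    records: Mapping[str, ChannelRecord],
    stim: StimulusTrain,
) -> Path:
    """Write data.csv, channels.csv and events.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for name, rec in records.items():
        t = np.arange(rec.values.size) / rec.fs
        frames.append(
            pd.DataFrame({"time_s": t, "channel_id": name, "value": rec.values})
        )
    pd.concat(frames, ignore_index=True).to_csv(out / "data.csv", index=False)
    pd.DataFrame(
        [
            {
                "channel_id": rec.channel_id,
                "emitter": rec.emitter,
                "detector": rec.detector,
                "distance_cm": rec.distance_cm,
                "role": rec.role,
                "ss_partner": rec.ss_partner or "",
            }
            for rec in records.values()
        ]
    ).to_csv(out / "channels.csv", index=False)
    pd.DataFrame(
        {
            "onset": stim.onsets,
            "duration": stim.durations,
            "trial_type": list(stim.conditions)
            if stim.conditions
            else ["task"] * stim.n_events,
        }
    ).to_csv(out / "events.tsv", sep="\t", index=False)
    return out


def read_dataset(
    path: str | Path, time_tolerance: float = 1e-6
) -> tuple[dict[str, ChannelRecord], pd.DataFrame, StimulusTrain]:
    """Read a dataset directory written by :func:`write_dataset`.

    Validates a uniform time base, resolves channel roles and SS pairings,
    and checks that every event lies inside the recording.
    """
    path = Path(path)
    data = pd.read_csv(path / "data.csv")
    chmap = pd.read_csv(path / "channels.csv", keep_default_na=False)
    events = pd.read_csv(path / "events.tsv", sep="\t")

    records: dict[str, ChannelRecord] = {}
    duration = 0.0
    for _, row in chmap.iterrows():
        name = row["channel_id"]
        sub = data[data["channel_id"] == name].sort_values("time_s")
        if sub.empty:
            raise ValueError(f"channel {name!r} declared in map but absent from data")
        t = sub["time_s"].to_numpy()
        dt = np.diff(t)
        if dt.size and (np.abs(dt - dt.mean()).max() > time_tolerance):
            raise ValueError(f"channel {name!r} has a non-uniform time base")
        fs = 1.0 / dt.mean() if dt.size else 1.0
        role = str(row["role"]).lower()
        role = "short" if role in ("short", "ss") else "long"
        partner = str(row.get("ss_partner", "")) or None
        records[name] = ChannelRecord(
            channel_id=name,
            values=sub["value"].to_numpy(),
            fs=fs,
            distance_cm=float(row["distance_cm"]),
            role=role,
            ss_partner=partner,
            emitter=int(row.get("emitter", 0) or 0),
            detector=int(row.get("detector", 0) or 0),
        )
        duration = max(duration, t[-1] + 1.0 / fs)
    for name, rec in records.items():
        if rec.role == "long" and rec.ss_partner and rec.ss_partner not in records:
            raise ValueError(
                f"long channel {name!r} references missing SS partner "
                f"{rec.ss_partner!r}"
            )
    for i, row in events.iterrows():
        if row["onset"] + row["duration"] > duration + 1e-9:
            raise ValueError(f"event row {i} extends past the recording end")
    stim = StimulusTrain(
        onsets=events["onset"].to_numpy(float),
        durations=events["duration"].to_numpy(float),
        conditions=tuple(events["trial_type"].astype(str)),
    )
    return records, chmap, stim


def run_pipeline(
    config: RunConfig,
    dataset_dir: str | Path,
    out_dir: str | Path,
) -> dict:
    """Run the full denoising pipeline on a dataset directory.

    Writes per-channel extracted HR series (extracted.csv), a metrics table
    (metrics.csv) and a JSON summary of estimated frequencies and final
    coefficients; returns the summary dict.
    """
    records, _, stim = read_dataset(dataset_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    long_records = {k: v for k, v in records.items() if v.role == "long"}
    if not long_records:
        raise ValueError("dataset contains no long channels")
    fs = next(iter(long_records.values())).fs
    n = next(iter(long_records.values())).values.size
    exp = expected_hr(stim, fs, n)

    detrended = {
        name: detrend_poly(rec.values, config.detrend_order)
        for name, rec in records.items()
    }

    rest_sl = slice(
        int(np.floor(config.rest_window_s[0] * fs)),
        int(np.floor(config.rest_window_s[1] * fs)),
    )
    bands = SearchBands()
    extracted = {}
    freq_log = {}
    coef_log = {}
    metrics_rows = []
    for name, rec in long_records.items():
        y = detrended[name]
        if config.freq_mode == "fixed":
            freqs = fixed_frequencies(fs)
        else:
            freqs = estimate_frequencies(y[rest_sl], fs, bands)
        if config.use_ss:
            if not rec.ss_partner:
                raise ValueError(
                    f"SS regression requested but long channel {name!r} has "
                    "no SS partner"
                )
            result = run_filter(
                y,
                detrended[rec.ss_partner],
                exp,
                freqs,
                lam=config.lam,
                init=RLSInit(delta=config.init_delta),
                with_cosines=config.with_cosines,
            )
        else:
            result = run_filter_no_ss(
                y,
                exp,
                freqs,
                lam=config.lam,
                init=RLSInit(delta=config.init_delta),
                with_cosines=config.with_cosines,
            )
        extracted[name] = result.extracted_hr
        freq_log[name] = {
            "mayer": freqs.f_mayer,
            "respiratory": freqs.f_resp,
            "cardiac": freqs.f_cardiac,
            "fallback": list(freqs.fallback),
        }
        coef_log[name] = dict(
            zip(result.regressor_names, result.final_coefficients.tolist())
        )
        raw_cnr = cnr(y, stim.onsets, fs, config.task_window_s, config.rest_cnr_window_s)
        filt_cnr = cnr(
            result.extracted_hr,
            stim.onsets,
            fs,
            config.task_window_s,
            config.rest_cnr_window_s,
        )
        metrics_rows.append(
            {
                "channel_id": name,
                "cnr_raw": raw_cnr.value,
                "cnr_filtered": filt_cnr.value,
                "improved": filt_cnr.value > raw_cnr.value,
                "t_value": tvalue_vs_expected(result.extracted_hr, exp.u),
                "corr_expected": pearson(result.extracted_hr, exp.u),
            }
        )

    metrics_df = pd.DataFrame(metrics_rows)
    improvement = improvement_fraction(
        {r["channel_id"]: r["cnr_filtered"] for r in metrics_rows},
        {r["channel_id"]: r["cnr_raw"] for r in metrics_rows},
    )

    t = np.arange(n) / fs
    ext_df = pd.DataFrame({"time_s": t, **extracted})
    ext_df.to_csv(out / "extracted.csv", index=False, float_format="%.10g")
    metrics_df.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
    summary = {
        "config": config.model_dump(),
        "frequencies": freq_log,
        "final_coefficients": coef_log,
        "improvement_fraction_pct": improvement,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
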