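# nirsrls

Adaptive filtering of physiological noise in functional near-infrared
spectroscopy (fNIRS) time series, built around recursive least squares
(RLS) with an exponential forgetting factor.

## The problem

Continuous-wave fNIRS measures cortical oxy-/deoxy-hemoglobin changes
(ΔHbO, ΔHbR) optically through the scalp. Long-separation channels
(~3 cm emitter–detector distance) mix the evoked hemodynamic response
(HR) with cardiac (~1 Hz), respiratory (~0.25 Hz) and Mayer-wave
(~0.1 Hz) oscillations, superficial scalp hemodynamics and slow drift.
At slow sampling rates (the targeted protocol runs at 1.81 Hz, Nyquist
0.905 Hz) the cardiac rhythm aliases close to the band of interest, so
plain low-pass filtering cannot separate it cleanly.

`nirsrls` addresses this for anyone analysing block-design fNIRS
experiments, online or offline: the coefficients are tracked sample by
sample, so the same code serves real-time denoising and retrospective
analysis.

## The model

A long channel `y(t)` is modeled per sample as

```
y(t) = a1 u(t) + a2 Δu(t) + a3 Δ²u(t) + a4 y_ss(t)
       + Σ_{m=1..q} b_m sin(2π f_m t) + b0 + ε(t)
```

where `u(t)` is the expected HR (stimulus boxcar convolved with the
canonical double-gamma impulse response), `Δu`/`Δ²u` its finite-difference
derivatives, `y_ss(t)` a short-separation (≤1 cm) channel that sees only
superficial noise, the `q = 3` sinusoids model the physiological rhythms at
frequencies `f_m` estimated per experiment from the initial 20 s rest by
FFT peak picking, and `b0` absorbs the baseline. The coefficient vector
β = [a1..a4, b1..bq, b0] minimises the exponentially forgotten cost
`Σ_k λ^(t−k) (y(k) − φ(k)ᵀβ)²` and is tracked by the standard RLS
recursion with gain `Pφ/(λ + φᵀPφ)` (default λ = 0.99, P(0) = 1e6·I). The
denoised HR is the task-locked part `â1 u + â2 Δu + â3 Δ²u`.

Baselines for comparison: a zero-phase Butterworth low-pass/band-pass
filter, and a Kalman filter over a 15-Gaussian canonical-HR basis plus SS
regressor (random-walk states, initial/process covariance diagonals 1e−1
and 5e−4). Evaluation metrics: per-trial contrast-to-noise ratio
`CNR = (mean(task) − mean(rest)) / sqrt(var(task) + var(rest))` with task
window 4–14 s and rest window −6–0 s around each onset,
channel-improvement percentages, Pearson correlation, and robust
(bisquare IRLS) regression t-values against the expected HR.

A synthetic generator produces the validation mixture (HR + three
sinusoids + white noise) and full multi-channel experiments (shared
superficial noise, drift, paired SS channels) with exact ground truth, and
a modified Beer–Lambert module converts dual-wavelength intensities to
ΔHbO/ΔHbR.

## Worked example

```python
import numpy as np
from nirsrls import (make_oscillator_mixture, validation_mixture_config,
                     estimate_frequencies, run_filter_no_ss, pearson)
from nirsrls.hrf import block_paradigm_train, expected_hr

fs = 1.81
components, mixture, truth = make_oscillator_mixture(validation_mixture_config(seed=1))
rest = mixture[: int(20 * fs)]
freqs = estimate_frequencies(rest, fs)
print(f"estimated frequencies: Mayer {freqs.f_mayer:.3f} Hz, "
      f"respiratory {freqs.f_resp:.3f} Hz, cardiac {freqs.f_cardiac:.3f} Hz")

exp = expected_hr(block_paradigm_train(), fs, mixture.size)
result = run_filter_no_ss(mixture, exp, freqs, lam=0.99)
half = mixture.size // 2
r = pearson(result.extracted_hr[half:], components["hr"][half:])
rms = np.sqrt(np.mean((result.extracted_hr[half:] - components["hr"][half:])**2))
print(f"correlation of extracted vs true HR (final half): {r:.3f}")
print(f"RMS error of extracted HR (final half): {rms:.3f} (true HR peak 1.0)")
```

prints

```
estimated frequencies: Mayer 0.127 Hz, respiratory 0.262 Hz, cardiac 0.901 Hz
correlation of extracted vs true HR (final half): 0.981
RMS error of extracted HR (final half): 0.085 (true HR peak 1.0)
```

The generator placed tones at exactly 0.13, 0.26 and 0.9 Hz; each is
recovered to within one FFT bin (~0.0035 Hz) from just 36 rest samples,
and after the recursion converges the extracted HR tracks the true
blocked response closely despite the oscillations being of comparable
amplitude.

A command-line interface mirrors the pipeline:

```sh
nirsrls simulate --out dataset/ --n-channels 40 --seed 0
nirsrls filter --data dataset/ --out results/ --lambda 0.99 --freqs estimated
nirsrls compare --data dataset/ --out compare.csv --methods rlse,kalman,lpf
nirsrls metrics --data dataset/ --filtered results/extracted.csv --out metrics.csv
```

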