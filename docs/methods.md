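# Methods

## Observation model

Each long-separation channel is modeled per sample as a linear
combination of a task-locked subspace, nuisance regressors and a
baseline:

```
y(t) = a1 u(t) + a2 Δu(t) + a3 Δ²u(t) + a4 y_ss(t)
       + Σ_{m=1..3} b_m sin(2π f_m t) + b0 + ε(t)
```

Assumptions: the superficial contribution to a long channel is, up to a
scalar gain, the signal seen by its paired short-separation channel; the
physiological rhythms are narrow-band and well approximated by constant-
frequency sinusoids over one run; and the evoked response lies in the span
of the expected HR and its first two derivatives (the derivative terms
absorb small latency and dispersion mismatches between the canonical
kernel and the actual response).

The sinusoidal basis is sine-only with phase referenced to t = 0. An
arbitrary-phase oscillation is therefore not fully absorbable by a single
static coefficient; in practice the forgetting factor lets the coefficient
trajectory track the effective in-phase amplitude, and an optional
`with_cosines` switch adds cosine partners when static phase coverage is
wanted.

## Recursive estimation

The coefficient vector minimizes the exponentially weighted cost
`J(β, t) = ½ Σ_{k≤t} λ^(t−k) (y(k) − φ(k)ᵀ β)²`. The implemented
recursion is the standard minimizer of that cost:

```
k(t)  = P φ / (λ + φᵀ P φ)
β    ← β + k(t) (y − φᵀ β)
P    ← (P − k(t) φᵀ P) / λ,   then re-symmetrized as (P + Pᵀ)/2
```

Each incoming sample pair (φ(t), y(t)) updates the state exactly once, in
time order. Initialization is the uninformative β(0) = 0,
P(0) = δI with δ = 1e6; δ only matters for the first ~p samples.

Parameters that matter:

- **λ (forgetting factor)**, dimensionless in (0, 1], default 0.99. The
  effective memory is 1/(1−λ) samples (~55 s at 1.81 Hz): long enough to
  average over trials, short enough to track slow drifts in oscillation
  amplitude. λ = 1 reduces to ordinary recursive least squares and is used
  wherever an exact batch-OLS equivalence is exercised.
- **δ (initial covariance scale)**, default 1e6: uninformative prior.
- **q = 3** sinusoids (Mayer, respiratory, cardiac).

The extracted HR is `â1 u + â2 Δu + â3 Δ²u` evaluated with the
instantaneous coefficient trajectory, matching the online character of the
recursion; a `coefficient_mode="final"` option re-applies the converged
coefficients to the whole record for offline use. The per-regressor
component series are accumulated in a fixed order so that they sum to the
fitted signal exactly (bit-for-bit), which the tests rely on.

Run-to-run state is never reset between trials; the baseline coefficient
b0 tracks slow offset changes through the forgetting factor instead of a
per-trial re-initialization (the alternative would be to reset β/P at each
onset; we document but do not implement it).

## Frequency estimation

The three physiological frequencies are estimated per channel from the
initial 20 s rest segment: the mean-removed segment is zero-padded to the
next power of two ≥ 8× its length, and within each search band (Mayer
0.05–0.2 Hz, respiratory 0.2–0.5 Hz, cardiac 0.5–min(1.5, Nyquist) Hz) the
frequency of the maximum DFT magnitude is taken. The peak is the argmax
bin — no quadratic interpolation — for exact reproducibility; resolution
is fs/N_fft (~0.0035 Hz for a 36-sample segment at 1.81 Hz).

A band falls back to the nominal fixed value (0.1, 0.25, 1 Hz) when its
peak magnitude is below 5× the median spectral magnitude. The threshold
was placed between the two regimes the generator produces at 20 s
segments: in-band tones of the default amplitudes give peak/floor ratios
of 6.6 or more, while pure white noise stays below 3.8 (200-seed
Monte-Carlo). Fixed frequencies are clipped to 98% of Nyquist, not to
Nyquist itself: a phase-zero sine sampled exactly at fs/2 is identically
zero and would leave its coefficient unidentifiable.

Known limitation: a real tone within ~0.03 Hz of Nyquist interferes with
its own spectral image, and the one-bin localization guarantee degrades
(at fs = 1.81 Hz this affects the 0.87–0.905 Hz corner of the cardiac
band). The same imaging effect is why heart rate is resolved near
0.8–0.9 Hz rather than 1 Hz at this sampling rate.

## Expected response

The default expected-HR generator convolves the stimulus boxcar with the
canonical double-gamma impulse response — gamma-density difference with
peak at 6 s, undershoot at 16 s, undershoot ratio 1/6, kernel
peak-normalized to 1 — behind a pluggable kernel interface, so a
subject-specific impulse response (e.g. one identified from pilot data)
can be substituted without touching the filter. Derivatives are central
finite differences scaled by fs and fs², one-sided at the boundaries;
`u` is not rescaled after convolution so that superposition of stimulus
trains remains exactly linear.

## Comparators

- **Low-pass / band-pass**: 4th-order Butterworth, zero-phase
  (forward–backward) application. The filter family and order are a
  documented default, configurable in `FilterSpec`.
- **Kalman filter**: random-walk states over 15 Gaussian bumps spanning a
  30 s trial window (width = spacing/1.5, columns max-normalized, rows
  trial-locked: the basis restarts at each onset) plus one SS coefficient.
  Initial covariance diag 1e−1, process noise diag 5e−4; the measurement
  noise variance is not pinned by the comparison configuration we follow
  and defaults to 1e−3. With zero process noise the filter reduces to
  recursive Bayesian regression and matches the batch normal-equations
  solution, which the tests use as the oracle.

## Metrics

Per-trial CNR uses half-open windows [4, 14) s (task) and [−6, 0) s
(rest) around each onset, converted to samples by floor; sample variances
use ddof = 1; trials whose windows leave the recording are skipped and
flagged, and a trial with zero variance in both windows reports NaN.
Channel aggregation is the mean over retained trials (a pooled-window
alternative would weight trials by length; we keep the simple mean).
`improvement_fraction` counts strict inequalities — ties are not
improvements. Robust t-values use IRLS with the Tukey bisquare weight
(c = 4.685) and MAD/0.6745 scale via statsmodels' RLM; an affinely exact
fit short-circuits to a signed infinity before IRLS would divide by a
zero scale.

## Synthetic data

The validation mixture emulates the component-separation study condition:
a block-design expected HR (20 s rest, then ten 10 s-task/20 s-rest
trials, 320 s ≈ 579 samples at 1.81 Hz) at unit peak amplitude, sinusoids
at 0.13/0.26/0.9 Hz with amplitudes 0.5/0.3/0.4 (Mayer/respiratory/
cardiac; amplitudes of comparable magnitude keep the decomposition
non-trivial) and white noise of SD 1e−4. Oscillator phases default to 0,
matching the sine-only basis.

The multi-channel experiment adds what the mixture lacks: a shared
superficial process (low-pass-filtered Gaussian noise, 0.1 Hz cutoff,
SD 0.3) entering each long channel through a gain (default 0.6) and its
paired SS channel at unit gain; degree-4 polynomial drift with random
coefficients (SD 0.1); and per-channel white noise (SD 0.05, a
realistically poor single-trial SNR against the unit-peak HR). Sample
count is floor(duration × fs); timestamps start at 0.

What the generator does **not** emulate: motion artifacts, heteroscedastic
or 1/f instrument noise, frequency drift within a run, nonlinear
superposition of responses, or optical path effects (channels are
generated directly in concentration units). Passing tests therefore
demonstrate correctness of the estimator under its own model class and
graceful behavior under model mismatch in phase/frequency — not
performance on motion-contaminated recordings.

## Numerical choices

- FFT zero-padding to ≥8× segment length; argmax-bin peak, ties broken by
  the lower frequency (first argmax).
- RLS covariance re-symmetrized every step; positive-definiteness is a
  tested invariant at λ = 1.
- Polynomial detrending solves least squares on a Vandermonde design over
  a standardized abscissa for conditioning.
- MBLL: OD uses log base 10; default extinction coefficients follow the
  compiled Gratzer/Cope hemoglobin spectra (1/(mM·cm) at 760/830 nm) and
  DPF = 6.0 for both wavelengths — all configurable, since published
  protocols vary. The 2×2 system is rejected when its condition number
  exceeds 1e8. Note that ΔOD averages to exactly zero over the baseline
  window only when the baseline intensity is constant (log of the mean is
  not the mean of the log).
- Problem sizes in the test suite follow the study conditions (579-sample
  records, 20–40 channels, 10–20 Monte-Carlo seeds), which keeps the full
  suite in the tens of seconds on one core.

## Open design points resolved here

- The forgetting factor is not pinned by the protocol we target; 0.99 is
  the package default for slowly varying coefficients at ~1.8 Hz sampling.
- Whether HR extraction should use instantaneous or converged
  coefficients is exposed as `coefficient_mode` (default instantaneous).
- When a long channel has two candidate SS partners, the dataset's channel
  map decides; the simulator assigns partners round-robin and supports an
  explicit map.
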