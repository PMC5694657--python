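# Methods

## The SDI

The index quantifies how similar the statistical distribution of R-R
variability is across two consecutive time blocks. The uniformly
resampled R-R signal R(n) (4 Hz) is differenced, D(n) = |R(n+1) − R(n)|,
and at boundary index t the two blocks D(t−M+1..t) and D(t+1..t+M) are
histogrammed with a shared binning; the index is
1 − Σ P₁(i)P₂(i), scaled ×100.

Key properties the tests assert: the inner product of two probability
vectors lies in [0, 1] (Cauchy-Schwarz with ΣP = 1), so the SDI is
bounded in [0, 100]; it is symmetric in block order; and it depends on
each block only through its histogram, hence is invariant to permuting
values within a block. The index conflates *similarity* and *spread*:
two identical deterministic distributions score 0 while two identical
uniform distributions over n cells score (1 − 1/n) — that is the feature
that makes it track wakefulness, since an awake patient's D(n) spreads
over many cells.

Defaults: M = 128 (32 s at 4 Hz, so one value needs 64 s of data),
250 cells over [0, 0.5] s (cell width 0.002 s), evaluation hop 20
samples (5 s) so SDI timestamps land on the grid that expert scores and
monitor vital signs use. Values ≥ 0.5 s are accumulated in the last
cell rather than dropped, preserving ΣP = 1. Binning is half-open
[i·w, (i+1)·w) with the last cell closed, implemented by searching the
exact cell edges i·w (a floor(v/w) shortcut can misplace boundary
floats). The ×100 scaling is a config flag (`scale_to_100`) because the
index's closed-form reference values are conventionally quoted
unscaled; it defaults on. Whether successive evaluation windows overlap
is governed only by the hop; the 5 s default makes adjacent evaluations
share most of their data, which smooths the curve.

## Preprocessing and HRV extraction

ECG arrives as one- or two-column ASCII at a declared sampling rate
(500 Hz default). Mains interference is removed with an IIR notch
(60 Hz, quality 30) applied forward-backward: zero-phase filtering
matters because the quantity of interest is R-peak *timing*. Artifact
segments are masked per sample over half-open [start, end) intervals;
sample values are never altered. R peaks inside masked regions are
dropped, and resampled R-R values whose Berger window overlaps a masked
interval are marked invalid rather than interpolated — interpolation
would fabricate exactly the variability the SDI measures.

Peak detection is the classic band-pass (5-15 Hz) → differentiate →
square → 150 ms moving-window integrate chain with a global adaptive
threshold (15% of the 90th-percentile candidate energy), a 200 ms
refractory period, and refinement of each candidate to the raw-signal
argmax within ±75 ms. The global threshold assumes roughly stationary
QRS amplitude, which holds for the synthetic data and clean clinical
segments; records with large amplitude drift would need the full
running-threshold variant.

Berger resampling computes, at each 4 Hz grid time, the number of R-R
intervals falling fractionally in a window of two sample periods via
the piecewise-linear cumulative-interval function; the implied rate is
inverted to an interval value in seconds. The interval form (not
beats/min) is what the differencing consumes; the inversion is isolated
in `berger_resample` so a rate-domain variant can be swapped in. The
grid starts at the first peak, and samples whose window is not fully
covered are invalid, never extrapolated. The construction conserves
beats exactly: summed fractional counts over a tiling grid equal twice
the interval count.

## Synthetic data

The generator emulates the study conditions, not cardiac physiology.
A case is a four-stage DoA trajectory (defaults: 12% awake near 94,
10% monotone induction descent, 63% maintenance plateau fluctuating
inside 42-64 around 52, 15% monotone emergence to 88; durations scale
with the configured case length, 1800 s by default). R-R intervals are
drawn per beat from a Gaussian whose mean and SD interpolate linearly
in DoA between an awake regime (0.8 ± 0.05 s) and an anaesthesia regime
(1.0 ± 0.01 s), plus a respiratory sinus-arrhythmia sinusoid (0.25 Hz,
amplitude 0.02 s × DoA/100). The 5:1 SD contrast is the generator's
core premise — variability collapses under anaesthesia — and is
enforced as a parameter invariant. The ECG is a train of fixed
Gaussian-bump beat templates (P, Q, R, S, T; R amplitude 1 mV) at
500 Hz with optional additive 60 Hz interference and white noise, and
the template centres are returned as ground-truth peak times. Assessor
curves are the true trajectory seen through a small random lag and a
smooth (Gaussian-kernel low-pass, ~45 s correlation length) zero-mean
offset, both proportional to the assessor noise SD (5 score units by
default), clipped to [0, 100].

What this does *not* model: drug pharmacokinetics, ectopy and
arrhythmia, P/T-wave pathology, electrode motion artifacts, amplitude
drift, or systematic assessor bias. Passing tests therefore demonstrate
that the pipeline's machinery is correct and that the SDI separates the
variability regimes it was designed for — not that clinical performance
on hospital recordings is reproduced.

## Regression and ensembling

The network maps the scalar SDI at time t to the EACL score at t;
samples are pooled across model-building cases. Inputs and targets are
min-max scaled to [0, 1]; the architecture is 1-17-10-1 with tanh
hidden units and a linear output. Training is full-batch Adam
(lr 0.02) on mean squared error for at most 1000 epochs with a
70/15/15 train/validation/test split by seeded shuffle (sample-level by
default; case-level is a config option), keeping the weights of the
best validation epoch and stopping after 150 epochs without
improvement. Everything downstream of a seed is pure numpy, so a seed
pins the model bit-for-bit; the network is written in-module because
that determinism and the exact split/checkpoint contract are part of
the design. Predictions are clipped to [0, 100] after inverse scaling.

Cases whose SDI-EACL correlation is undefined or below 0.3 are excluded
before training (panel disagreement occasionally produces such cases,
and they only inject label noise). The ensemble trains ten members
differing only in seed and averages their pre-clip outputs; blind
cross-validation retrains from ten fresh seeds and reports per-repeat
mean ± SD of the pure-test correlation and MAE.

## Evaluation

Per case: Pearson r, MAE, and ROC/AUC where the reference is binarised
as conscious iff EACL > 65 (strict inequality; orientation: higher
scores indicate consciousness). Constant series and single-class
references raise typed "undefined" errors that the report surfaces as
excluded entries. Method comparisons use two-sided paired Student
t-tests over per-case metrics; identical methods are reported as "no
difference" (p = 1) rather than an error. Summaries are recomputed from
the per-case rows with sample SD.

## Problem sizes in the test battery

The stochastic acceptance checks run at sizes chosen to make their
Monte-Carlo margins comfortable on a single CPU: 20 full-pipeline cases
of 1800 s for the discriminability check; a 105-case cohort of 1200 s
cases (85 model-building / 20 pure-test), built directly from the R-R
process without waveform rendering, for the regression and
cross-validation checks; and 20 seeded ensemble-versus-member trials on
17-case sub-cohorts with a 250-epoch budget for the ensembling-helps
frequency check. Property suites use 1000 random block pairs.

## Known limitations

- The peak detector's global threshold assumes stationary QRS
  amplitude (see above).
- The SDI needs 64 s of valid resampled data before its first value;
  short or heavily masked records yield empty (warned) output.
- The EACL interpolation kernel is linear; hand-drawn curves digitised
  at coarse intervals may deserve a monotone spline instead.
- The regression input is the scalar SDI only; windowed or lagged
  feature variants would slot in at the feature-builder boundary in
  `doa_model` but are not implemented.
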