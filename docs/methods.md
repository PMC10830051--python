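# Methods

## The decoding model

The pipeline treats single-trial reaction time (RT) decoding as a
band-power regression problem. Labels are log RTs standardized per angular
disparity: RT distributions are right-skewed and their location depends
strongly on how far the figures are rotated, so `z = (log RT − μ_a)/σ_a`
with per-angle training statistics puts all trials on one difficulty-
adjusted scale. Statistics are population-SD (denominator *n*) for
reproducibility; they are fitted on training epochs only and applied
unchanged to validation and hold-out epochs, and predictions invert through
the same statistics back to milliseconds.

Per frequency band, SPoC solves `C_z w = λ C w` for the spatial filter
whose projected per-epoch variance maximally covaries with `z`. Epoch
covariances use per-epoch channel mean-centering (removing DC offsets that
filtering edges can introduce) and the T−1 denominator; `C` is shrunk
toward the scaled identity with γ = 1e−6 purely for numerical
invertibility. One component per band is kept — the one with the largest
**absolute** eigenvalue. The sign of λ is informative (power can rise or
fall with slower responses), so selecting by |λ| retains the strongest
comodulation either way; filters are sign-fixed so the largest-magnitude
pattern entry is positive, since `±w` describe the same source. Labels are
re-z-scored (population SD) inside the SPoC fit; this is an idempotent
normalization stated for determinism.

The regression is exact closed-form ridge with an unpenalized intercept on
features standardized by training statistics (so one λ grid is meaningful
for every participant). λ is tuned on three overlapping chronological
windows (length `floor(n/1.9)`, stride `floor(0.45 L)`, last window
anchored to `n`); each trains on its first `ceil(0.55 L)` samples and
validates on the rest, making the three validation blocks pairwise
disjoint and strictly after their training samples. The SPoC filters, label
scaler and feature scaler are fitted once on the full training set and only
λ is tuned in the windows; the per-window feature scaler is refit on the
window's training part. Grid: 25 log-uniform points on [10⁻¹, 10⁴]; ties
resolve to the smaller λ.

## Preprocessing

ICA (FastICA, seeded) is fitted on a 1 Hz high-passed copy of the
one-minute resting recording; rejection is config-driven (an explicit
component list) with an automatic fallback that flags components whose
time course correlates |r| ≥ 0.8 with a blink reference (the simulation's
ground-truth blink trace, else a low-passed frontal-channel average) —
visual inspection is not reproducible in software. Cleaning zeroes the
rejected source rows and reconstructs from the raw, unfiltered signal.

The filter bank is ten Hamming-window linear-phase FIR band-passes, 4 Hz
wide, centers 2–38 Hz in steps of 4 (the tenth center continues the
arithmetic progression; configurable). Filters are applied in a single
pass with group-delay compensation (symmetric taps, centered convolution)
so the net response is zero-phase; edges are reflect-padded by one filter
length. The transition band is 2 Hz per side, which places a tone 6 Hz off
a band's center well into the Hamming stop band (>50 dB).

Epochs are one per presentation phase — fixation `[fix_on, stim_on)` and
stimulus `[stim_on, response)`, half-open, 0-based. Retention drops
fixation epochs, incorrect and missing (timeout) responses, and trials
with RT < 700 ms (700 ms itself is retained); survivors are cropped to the
first 500 ms of the stimulus phase. Because retained RTs are ≥ 700 ms, the
500 ms window always ends ≥ 200 ms before the response, so the
motor-preparation guard is implied and asserted rather than applied as a
separate trim. The three rules commute; removal counts per rule are logged
and stored with the epochs.

## Evaluation and interpretation

The RT baseline predicts the training-set mean standardized RT per angle —
identically 0 — for every hold-out epoch, so its MAE is the mean |z| of
the hold-out labels. Inter-individual transfer applies one participant's
ridge coefficients to another participant's hold-out epochs, with the
"pre-processor bundle" (label scaler, SPoC filters, feature scaler) taken
either from the train or from the test participant; labels are
standardized with the same bundle used for the features so prediction and
target share a scale. With bundle and data from the same participant the
inter evaluation reduces exactly to the intra evaluation.

Paired differences across participants are tested with a percentile
bootstrap (resampling participants with replacement, 9999 iterations by
default) and the two-sided small-sample-corrected p-value
`2·min(#{d̄* ≤ 0}+1, #{d̄* ≥ 0}+1)/(B+1)`. At n = 40 this percentile
scheme is measurably anti-conservative (empirical type-I error ≈ 0.06–0.08
at nominal 0.05), a known small-sample property accepted here for its
simplicity.

SHAP values use the independent-features (interventional) value function,
which is exact and closed-form for linear models:
`φ_b = β_b (x_b − mean background x_b)` in standardized feature space with
the training features as background; additivity holds to machine
precision and the implementation is tested against an exhaustive
2¹⁰-coalition Shapley computation. Group importance is the median and MAD
across participants of per-participant mean |φ| per band, plus a band×band
mean absolute difference table. Forward-model patterns are
sign-indeterminate, so cross-participant averaging sign-aligns each
pattern with the running mean before averaging.

## The synthetic-data generator

The generator emulates the study conditions: 192 trials stratified
exactly over 4 angles × 2 mirror states, sampled without replacement from
a 384-pair pool; fixation 1000–3000 ms uniform; stimulus capped at 7500 ms
with timeouts flagged as missing responses; 32 channels at 1 kHz with
10/20 labels. RTs are log-normal, `log RT ~ N(b₀ + b₁·angle, σ)` truncated
to [1, 7500] ms, with defaults b₀ = log 1400 ms, b₁ = 0.004/deg, σ = 0.25
— chosen once as plausible for a mental-rotation task whose mean RTs grow
from ≈1.4 s at 0° to ≈2.6 s at 150°; accuracy decays mildly with angle
(0.97 → 0.85). No published RT distribution parameters exist for this
exact task variant, so these defaults are configurable, not calibrated.

EEG is a sum of: (i) planted band-limited sources whose variance inside
each stimulus epoch window is rescaled **exactly** to
`exp(base + α·z_trial)` — the comodulation is planted, not approximated —
and sits at baseline elsewhere (default: one 10 Hz source, α = 0.8,
RMS ≈ 10 µV); (ii) broadband 1–45 Hz background sources (4 × 8 µV) with
random topographies; (iii) white sensor noise (2 µV); (iv) Poisson-timed
blink transients (10/min, 120 µV, 300 ms Hann bumps) with a fixed frontal
topography, present in both task and resting sessions. All topographies,
per-epoch target variances, `z`, and blink events are written to a
ground-truth sidecar so recovery tests need no recomputation. One global
seed expands into independent substreams (schedule, behaviour, sources,
noise, artifacts). Event samples are integers on the sampling grid; at
1 kHz one sample is one millisecond.

What the generator does **not** emulate: volume-conduction head models
(topographies are random unit vectors, not dipolar maps), 1/f spectral
structure, non-stationary drifts, muscle artifacts, or inter-trial
dependencies. Passing recovery tests therefore demonstrates algorithmic
correctness under the planted model, not performance on real recordings.

## Problem sizes for verification experiments

Structural checks run at the full default scale (32 channels, 1 kHz,
192 trials). Cohort-level experiments run at reduced sizes chosen as this
package's desk-scale verification conditions: headline cohorts use
20 participants at 16 channels, 100 Hz, 96 trials with participant-specific
topographies and a 10-point λ grid; importance-recovery uses 10 replicate
cohorts of 20 participants at 8 channels, 64 trials; single-participant
pattern recovery uses 32 channels, 100 Hz, 192 trials with halved
background noise. At 100 Hz the 500 ms epoch window holds 50 samples; the
time-bandwidth product of a 4 Hz band over 500 ms — which is what controls
the variance of a band-power estimate — is unchanged from the 1 kHz case,
so the statistical difficulty of the decoding problem is preserved while
the covariance dimension (16 or 8 instead of 32) is reduced to match the
smaller epoch counts.

## On-disk formats and degenerate inputs

Raw sessions are written as 16-bit EDF (minimal built-in writer;
microvolts, one-second records, exact sample count in a JSON sidecar) with
BIDS-style `*_events.tsv`, `*_channels.tsv` and ground-truth JSON; reading
uses MNE's EDF reader, so round-trips cross an independent implementation
and are exact up to 16-bit quantization. Epoch containers are HDF5 with
per-band datasets and aligned metadata columns.

Degenerate inputs are handled explicitly: zero label variance or fewer
than two epochs per angle is an error; a zero MAD disables outlier removal
for that angle group; removing more than half an angle group warns and
proceeds; an empty retained-epoch set warns; rank-deficient ICA input
raises with the implicated channels; n < 20 training epochs is too small
for the sliding windows and raises.
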