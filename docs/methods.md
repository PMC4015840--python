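# Methods

## Model and assumptions

EMS filtering treats each time sample of an epoched multi-sensor
recording as an observed topography `x ∈ R^m` and asks how strongly it
expresses a target experimental effect. The effect is encoded by an
*objective function* `f(X_slice, y) → d ∈ R^m`, one coefficient per
sensor; the canonical objective is the difference of condition means.
The coefficient vector, normalized to unit Euclidean length, is applied
as a matched spatial filter by the dot product. Matched filtering is
SNR-optimal under i.i.d. sensor noise; real recordings violate that
assumption (spatially correlated noise), in which case the matched
filter is suboptimal but remains directly interpretable: the weight
vector *is* the effect topography, and for the difference of means the
unit-norm filter exactly maximizes `Σ_k y_k ⟨x_k, w⟩` over unit vectors
(`y = +1/N_A` or `−1/N_B`). An optional Fisher-style whitening step
(`whiten_filter`, shrinkage-regularized inverse noise covariance) trades
interpretability for separability; it is off in every default pipeline.

Cross-validation prevents circularity: the filter projected onto trial
`k` is computed from data that exclude trial `k` (or its whole fold).
Under leave-one-out the expected surrogate class difference is exactly
zero when no effect exists, because each trial is independent of its own
filter. The surrogate *distribution* under the null is skewed at low
sensor counts, so single-subject inference on surrogate aggregates
should use resampling (label permutation), not t-tests; the package
exposes seeded permutation of labels for that purpose and keeps formal
testing out of scope.

## Data model

Data are `channel × sample × trial`, with strictly uniform sample times
in seconds. Windows are half-open `[start_s, end_s)` and resolved by
direct comparison against the time vector (no index rounding), so
adjacent windows never double-count a sample. Mixed sensor groups with
different units (e.g. magnetometers vs. gradiometers) are refused by the
transforms unless the data are first z-scored per group
(`zscore_by_sensor_group`, population SD over the entire group block,
which yields exactly unit variance) or the groups filtered separately.

## Numerical choices

- **Degenerate filters.** A coefficient vector with norm below
  `1e-12 × max(1, ‖slice‖)` (scale-aware, to avoid false degeneracy on
  small-unit data) yields a zero filter, zero surrogate values and a
  degeneracy mask rather than an error — exact nulls legitimately
  produce them.
- **Unit-norm contract.** Every non-degenerate filter has norm 1 within
  1e-10.
- **Ties and floors in decoding.** The Gaussian naive-Bayes rule uses
  per-class sample variance with a floor of `1e-12 ×` the data variance
  (activations are logged); posterior ties go to condition A
  deterministically, for reproducibility.
- **Confidence band.** The effect course's band uses the Welch standard
  error and t quantile (default 99%).
- **Smoothing.** Decoding accuracy is smoothed with a centered boxcar
  (default 50 ms) truncated at the epoch edges, not padded.
- **Component metrics.** Peak latency is the time of maximum absolute
  value in the search window; duration is the temporal extent of the
  contiguous run around the peak staying at or above a configurable
  fraction (default 0.5) of the peak. These are declared defaults — the
  quantities have no single canonical definition.
- **Reaction-time predictor.** Samples within `[RT−200 ms, RT+50 ms]`
  (inclusive bounds) are coded −1 around the first response and +1
  around the second; on overlap the later response wins. The regression
  objective fits one OLS slope per channel on the flattened
  trial × sample matrix (single regressor plus intercept), producing one
  stationary filter.
- **Cross-validation.** LOO is the default. LOOPC pairs one trial per
  condition per fold (seeded pairing) and requires balanced counts;
  k-fold is label-stratified and seeded; leave-one-subject-out
  pre-computes per-subject class means before differencing across the
  retained subjects. Fold filters are always computed directly from the
  fold-complement data (no running-sum shortcuts), so corrupting a
  fold's held-out trials cannot change its filters even in the last bit.

## SNR and the trials-averaged curve

SNR of a condition-difference course is
`10·log10((RMS_signal/SD_noise)²)` with the RMS over the signal window
and the (n−1)-denominator SD over a disjoint baseline window.
`snr_vs_trial_count` runs the transform once on the full dataset and
then, per trial count `n`, averages seeded random subsets of `n`
surrogate courses per condition before scoring — the SNR of an
`n`-trial average. This matches the quantity's meaning ("SNR as a
function of the number of trials averaged together") and isolates the
averaging benefit from filter quality; a `refit=True` variant re-estimates
the filters on every subset for users who want the combined effect of
fewer trials on both estimation and averaging. The ROI baseline replaces
the estimated filter with a fixed uniform-weight mask normalized to unit
length.

## Synthetic data: what it emulates, what it does not

The generator produces i.i.d. Gaussian sensor noise (optionally
channel-correlated via a supplied correlation matrix, to exercise
whitening) plus planted components: `amplitude × topography × Hann
pulse` over a named window, on condition-1 trials only (class-specific)
or all trials. The raised-cosine pulse gives each component a unique,
well-defined peak at the window center, which is what the latency
metrics recover. Options cover per-trial latency jitter (Gaussian,
clipped to the epoch), a second sensor group on a different unit scale
(to exercise z-scoring), and reaction-time coupling: log-normal RT1 and
RT2 per trial, an early component whose duration grows with RT1, a late
component whose latency grows with RT1, and response-locked lateralized
activity of opposite sign around the two responses.

Default study conditions used by the test suite, chosen once as
desk-scale analogues of a small two-condition sensor-array experiment:
20 sensors, 100 Hz, 1 s epochs starting 0.2 s before onset, 30–60
trials per condition (real per-condition counts in comparable dual-task
recordings run ~30–75), unit noise SD. The SNR-comparison scenario
plants a smooth two-region opposite-sign topography (Gaussian humps,
`‖topo‖ ≈ 3.3`) with amplitude 1 and noise SD 1.5 — single-trial
surrogate SNR of roughly 2 dB, i.e. individual trials barely rise above
baseline — against a 5-channel contiguous uniform ROI at the positive
peak. That ROI instantiates both standard ROI failure modes: it omits
the opposite-sign region entirely and weights a graded profile equally.

What the generator does **not** emulate: biophysical forward models,
realistic MEG noise spectra (1/f, line noise), artifacts, non-stationary
noise, or inter-subject anatomical variability. Passing tests therefore
demonstrate the algorithmic contracts (no leakage, unit norms, null
unbiasedness, ordering of EMS vs. ROI under distributed effects), not
performance on any particular real recording.

## Problem sizes

The test suite runs everything at desk scale: null-unbiasedness uses
200 replicates of 20 × 50 × 40 arrays; the SNR comparison uses
100 repetitions per trial count on a 20 × 60 × 120 array; decoding uses
30 trials per condition. These sizes were chosen so the full suite
completes in well under a minute while keeping Monte-Carlo errors small
relative to the tested margins.

## Known limitations

- Optimality of the cross-validated filter is established only for the
  difference-of-means objective; other objectives are supported but
  their statistical properties must be assessed per case.
- Surrogate time courses within a subject are mutually dependent
  (filters share trials); only per-subject aggregates are independent.
- Multiple comparisons across sensors are eliminated, but comparisons
  across time samples remain the user's responsibility.
- The HDF5 container stores epoched data only; continuous recordings,
  artifact handling and vendor formats are upstream of this package.
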