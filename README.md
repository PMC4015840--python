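# emsfilter

Effect-matched spatial (EMS) filtering for epoched multi-sensor time
series — EEG, MEG, ECoG and kin.

## The problem

Multi-sensor recordings are highly redundant: any experimental effect,
however focal, appears on many sensors at once, and the sensors that
carry it change over the course of a trial. Picking one sensor, or
averaging a fixed "region of interest" (ROI), ignores both the graded
distribution of the effect over the array and its spatial evolution in
time. EMS filtering instead reduces each trial's `channel × time` matrix
to a **single surrogate time course that tracks the experimental effect
itself**, in the original measurement units.

## The method

Let `X` be the `m × n × p` data array (sensors × samples × trials) with
per-trial condition labels `y`. An *objective function* `f` maps the
data at one time sample (an `m × p` slice) plus `y` to one coefficient
per sensor — canonically the difference of the two condition means,

    d_j = ⟨x_A⟩_j − ⟨x_B⟩_j            (per channel, at sample j).

At each sample the coefficient vector is normalized to unit length,
`ŵ_j = d_j / ‖d_j‖`, and each trial's topography is projected onto it by
the dot product, `s_jk = ŵ_jᵀ x_jk`, which preserves units because
`‖ŵ‖ = 1`. To avoid circularity, the filter applied to trial `k` is
estimated from **all trials except `k`** (leave-one-out; per-condition,
k-fold and leave-one-subject-out schemes are also provided). For the
difference of means the unit-norm filter is the exact maximizer of the
weighted projection sum `Σ_k y_k ⟨x_k, w⟩` with `y = ±1/N_{A,B}`, and
under i.i.d. noise it is the SNR-optimal matched filter for the effect.

The package also provides stationary-template variants (windowed mean
difference, temporal amplitude difference, regression of each sensor on
a trial × sample predictor such as a reaction-time-locked ±1 code),
SNR estimation in dB, SNR-vs-trial-count curves, ROI baseline filters,
nested naive-Bayes time-resolved decoding, component latency/duration
metrics, filter-similarity diagnostics, a synthetic-data generator with
known ground truth, an HDF5 epochs container, and a CLI.

## Worked example

```python
import numpy as np
from emsfilter import EMS, Component, ConditionPair, EffectScenario, gen_effect_dataset

# plant a graded, two-region, opposite-sign topography on condition-1 trials
topo = np.zeros(20)
topo[2:7] = [0.5, 1.0, 1.5, 1.0, 0.5]
topo[12:17] = [-0.5, -1.0, -1.5, -1.0, -0.5]
scenario = EffectScenario(
    n_channels=20, n_samples=100, n_trials_per_class=40,
    sample_rate=100.0, tmin=-0.2, noise_sd=1.0, seed=42,
    components=[Component(topography=topo, window=(0.15, 0.35), amplitude=1.0)],
)
dataset, _ = gen_effect_dataset(scenario)

model = EMS(dataset, pair=ConditionPair(1, 0))   # effect vs control
results = model.fit()
print(results.summary())
report = results.snr(signal_window=(0.15, 0.35), noise_window=(-0.2, 0.0))
print(f"SNR: {report.snr_db:.2f} dB")
```

Output:

```
EMS filtering results
======================================================
channels                    20
samples                     100
trials                      80
objective                   mean_difference
cross-validation            loo
folds                       80
degenerate filters          0
conditions (A vs B)         1 vs 0
peak |effect|               +3.06
peak latency (s)            0.2500
ci half-width at peak       0.5876 (99%)
======================================================
SNR: 16.23 dB
```

The peak effect of +3.06 (in the data's units) at 0.25 s is the
difference of the surrogate class means at the center of the planted
window — close to the planted value `amplitude × ‖topo‖ ≈ 3.3` at the
pulse peak, attenuated slightly by filter-estimation noise. The 16 dB
SNR says the condition-difference course in the effect window is ~6×
the baseline standard deviation in RMS terms. `results.surrogates`
holds the single-trial courses, `results.filters` the unit-norm filter
set, and `results.decode()` runs nested naive-Bayes decoding.

The same pipeline is available from the shell:

```sh
emsfilter simulate epochs.h5 --seed 42 --channels 20 --samples 100 --trials-per-class 40
emsfilter transform epochs.h5 results.h5 --pair 1,0
emsfilter snr results.h5 --pair 1,0 --signal-window 0.15,0.35 --noise-window -0.2,0.0
```

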