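"""Seeded generators of epoched multi-sensor datasets with known ground
truth.

The generators emulate the structure of evoked multi-sensor recordings at
desk scale: i.i.d. Gaussian sensor noise, condition-specific topographies
planted in named time windows (with optional latency jitter), mixed
sensor groups on different unit scales, and response-locked lateralized
components tied to per-trial reaction times.  Every generator is a pure
function of its seed and scenario, and the returned ground-truth record
is sufficient to compute analytic oracles without re-running it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import EMSError, EpochedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Component",
    "EffectScenario",
    "RTCoupling",
    "gen_null_dataset",
    "gen_effect_dataset",
    "gen_rt_dataset",
]


def _hann_pulse(times: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Raised-cosine (Hann) pulse supported on [start, stop), peak at the
    center — gives every planted component a unique peak latency."""
    prof = np.zeros_like(times)
    width = stop - start
    if width <= 0:
        return prof
    in_win = (times >= start) & (times < stop)
    phase = (times[in_win] - start) / width
    prof[in_win] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return prof


@dataclass
class RTCoupling:
    """How a component's timing depends on the trial's first reaction time.

    ``latency_slope``: seconds of added onset latency per second of RT1
    (serial-stage behavior); ``duration_slope``: seconds of added duration
    per second of RT1 (sensory-buffer behavior).
    """

    latency_slope: float = 0.0
    duration_slope: float = 0.0


@dataclass
class Component:
    """One planted spatio-temporal component."""

    topography: np.ndarray
    window: tuple[float, float]
    amplitude: float = 1.0
    class_specific: bool = True
    latency_jitter_sd: float = 0.0
    rt_coupling: RTCoupling | None = None

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=float)
        if not np.isfinite(self.topography).all():
            raise EMSError("component topography must be finite")


@dataclass
class EffectScenario:
    """Parameters of a synthetic evoked-effect recording.

    Defaults describe a small two-condition experiment: 20 sensors in one
    group, 100 Hz sampling, a 1 s epoch starting 0.2 s before stimulus
    onset, 30 trials per condition and unit-variance sensor noise.
    """

    n_channels: int = 20
    n_samples: int = 100
    n_trials_per_class: int = 30
    sample_rate: float = 100.0
    tmin: float = -0.2
    noise_sd: float = 1.0
    components: list[Component] = field(default_factory=list)
    #: optional second sensor group: (channel mask, multiplicative scale, unit)
    group2: tuple[np.ndarray, float, str] | None = None
    #: optional channel-correlation matrix for non-i.i.d. noise
    noise_corr: np.ndarray | None = None
    seed: int = 0

    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sample_rate

    def validate(self) -> None:
        if min(self.n_channels, self.n_samples, self.n_trials_per_class) < 1:
            raise EMSError("scenario dimensions must be strictly positive")
        if self.noise_sd <= 0:
            raise EMSError("noise_sd must be positive")
        t = self.times()
        t_end = t[-1] + 1.0 / self.sample_rate
        for c in self.components:
            if c.topography.size != self.n_channels:
                raise EMSError("component topography length != n_channels")
            if c.window[0] < t[0] - 1e-9 or c.window[1] > t_end + 1e-9:
                raise EMSError(f"component window {c.window} outside the epoch")


def gen_null_dataset(
    n_channels: int, n_samples: int, n_trials: int, seed: int,
    sample_rate: float = 100.0, tmin: float = 0.0,
) -> EpochedDataset:
    """Pure i.i.d. standard Gaussian data with random half/half labels.

    No planted structure: the ground truth is that every effect estimate
    should average to zero.
    """
    if min(n_channels, n_samples, n_trials) < 1:
        raise EMSError("dimensions must be strictly positive")
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_channels, n_samples, n_trials))
    labels = np.zeros(n_trials, dtype=int)
    labels[n_trials // 2:] = 1
    labels = rng.permutation(labels)
    times = tmin + np.arange(n_samples) / sample_rate
    return EpochedDataset(data=data, times=times, labels=labels)


def _noise(rng: np.ndarray, scenario: EffectScenario) -> np.ndarray:
    shape = (scenario.n_channels, scenario.n_samples, 2 * scenario.n_trials_per_class)
    z = rng.standard_normal(shape) * scenario.noise_sd
    if scenario.noise_corr is not None:
        corr = np.asarray(scenario.noise_corr, dtype=float)
        chol = np.linalg.cholesky(corr)
        z = np.einsum("ci,ijt->cjt", chol, z)
    return z


def gen_effect_dataset(
    scenario: EffectScenario,
) -> tuple[EpochedDataset, dict]:
    """Gaussian noise plus planted condition-specific topographies.

    Class-specific components are added (amplitude x topography x Hann
    pulse over the window, onset optionally jittered per trial) to
    condition-1 trials only; non-class-specific components go into every
    trial.  Returns the dataset and a ground-truth record with exact
    per-trial onsets, pulse centers, topographies and class assignments.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    p = 2 * scenario.n_trials_per_class
    times = scenario.times()
    data = _noise(rng, scenario)
    labels = np.zeros(p, dtype=int)
    labels[scenario.n_trials_per_class:] = 1
    labels = rng.permutation(labels)

    epoch_start = times[0]
    epoch_end = times[-1] + 1.0 / scenario.sample_rate
    truth: dict = {
        "labels": labels.copy(),
        "times": times.copy(),
        "components": [],
    }
    for ci, comp in enumerate(scenario.components):
        start0, stop0 = comp.window
        width = stop0 - start0
        onsets = np.full(p, start0)
        if comp.latency_jitter_sd > 0:
            onsets = onsets + rng.normal(0.0, comp.latency_jitter_sd, size=p)
            clipped = np.clip(onsets, epoch_start, epoch_end - width)
            if not np.array_equal(clipped, onsets):
                logger.info(
                    "component %d: %d jittered windows clipped to the epoch",
                    ci, int((clipped != onsets).sum()),
                )
            onsets = clipped
        target = labels == 1 if comp.class_specific else np.ones(p, dtype=bool)
        for k in np.flatnonzero(target):
            prof = _hann_pulse(times, onsets[k], onsets[k] + width)
            data[:, :, k] += comp.amplitude * np.outer(comp.topography, prof)
        truth["components"].append(
            {
                "topography": comp.topography.copy(),
                "amplitude": comp.amplitude,
                "window": tuple(comp.window),
                "class_specific": comp.class_specific,
                "onsets": onsets.copy(),
                "centers": onsets + width / 2.0,
                "target_trials": np.flatnonzero(target),
            }
        )

    channel_groups = np.zeros(scenario.n_channels, dtype=int)
    units = {0: "au"}
    if scenario.group2 is not None:
        mask, scale, unit = scenario.group2
        mask = np.asarray(mask, dtype=bool)
        data[mask] *= scale
        channel_groups[mask] = 1
        units[1] = unit
        truth["group2"] = {"mask": mask.copy(), "scale": scale, "unit": unit}
    ds = EpochedDataset(
        data=data,
        times=times,
        labels=labels,
        channel_groups=channel_groups,
        units=units,
    )
    return ds, truth


def gen_rt_dataset(
    scenario: EffectScenario,
    rt1_median: float = 0.45,
    rt1_sigma: float = 0.25,
    gap_median: float = 0.35,
    gap_sigma: float = 0.20,
    early_topo: np.ndarray | None = None,
    late_topo: np.ndarray | None = None,
    lateralized_topo: np.ndarray | None = None,
    early_onset: float = 0.10,
    early_base_duration: float = 0.10,
    early_coupling: RTCoupling | None = None,
    late_base_latency: float = 0.15,
    late_coupling: RTCoupling | None = None,
    late_duration: float = 0.15,
    response_amp: float = 1.0,
    max_retries: int = 100,
) -> tuple[EpochedDataset, dict]:
    """Dual-task-like dataset whose component timing tracks reaction times.

    Per trial, RT1 is drawn log-normal (median ``rt1_median``) and RT2 =
    RT1 + a log-normal gap; trials whose events would fall outside the
    epoch are redrawn (bounded retries).  Planted on every trial:

    - an *early* component at a fixed onset whose duration grows with RT1
      (sensory-buffer behavior),
    - a *late* component of fixed duration whose latency grows with RT1
      (serial-stage behavior),
    - response-locked lateralized activity: ``-lateralized_topo`` in the
      window around RT1 and ``+lateralized_topo`` around RT2, mirroring
      responses made with opposite hands.

    Returns the dataset (covariates ``rt1``, ``rt2``) and a ground-truth
    record with all planted latencies, durations and topographies.
    """
    scenario.validate()
    if early_coupling is None:
        early_coupling = RTCoupling(duration_slope=0.5)
    if late_coupling is None:
        late_coupling = RTCoupling(latency_slope=1.0)
    early_duration_slope = early_coupling.duration_slope
    late_latency_slope = late_coupling.latency_slope
    rng = np.random.default_rng(scenario.seed)
    p = 2 * scenario.n_trials_per_class
    times = scenario.times()
    epoch_end = times[-1] + 1.0 / scenario.sample_rate
    m = scenario.n_channels

    def default_topo(lo: int, hi: int, sign: float = 1.0) -> np.ndarray:
        t = np.zeros(m)
        t[lo:hi] = sign
        return t / np.linalg.norm(t)

    early_topo = (
        np.asarray(early_topo, dtype=float)
        if early_topo is not None
        else default_topo(0, max(1, m // 4))
    )
    late_topo = (
        np.asarray(late_topo, dtype=float)
        if late_topo is not None
        else default_topo(max(1, m // 2), max(2, 3 * m // 4))
    )
    if lateralized_topo is None:
        lateralized_topo = np.zeros(m)
        lateralized_topo[: m // 2] = 1.0
        lateralized_topo[m // 2:] = -1.0
        lateralized_topo /= np.linalg.norm(lateralized_topo)
    else:
        lateralized_topo = np.asarray(lateralized_topo, dtype=float)

    mu1 = np.log(rt1_median)
    mug = np.log(gap_median)
    rt1 = np.empty(p)
    rt2 = np.empty(p)
    for k in range(p):
        for attempt in range(max_retries):
            r1 = float(rng.lognormal(mu1, rt1_sigma))
            r2 = r1 + float(rng.lognormal(mug, gap_sigma))
            late_lat = late_base_latency + late_latency_slope * r1
            if (
                r2 + 0.05 < epoch_end
                and late_lat + late_duration < epoch_end
                and early_onset + early_base_duration + early_duration_slope * r1
                < epoch_end
            ):
                rt1[k], rt2[k] = r1, r2
                break
        else:
            logger.info("trial %d: RT redraw retries exhausted; using median", k)
            rt1[k] = rt1_median
            rt2[k] = rt1_median + gap_median

    data = _noise(rng, scenario)
    labels = np.zeros(p, dtype=int)
    labels[scenario.n_trials_per_class:] = 1
    labels = rng.permutation(labels)

    amp = scenario.components[0].amplitude if scenario.components else 1.0
    early_durations = early_base_duration + early_duration_slope * rt1
    late_latencies = late_base_latency + late_latency_slope * rt1
    for k in range(p):
        prof_e = _hann_pulse(times, early_onset, early_onset + early_durations[k])
        data[:, :, k] += amp * np.outer(early_topo, prof_e)
        prof_l = _hann_pulse(times, late_latencies[k], late_latencies[k] + late_duration)
        data[:, :, k] += amp * np.outer(late_topo, prof_l)
        prof_r1 = _hann_pulse(times, rt1[k] - 0.2, rt1[k] + 0.05)
        prof_r2 = _hann_pulse(times, rt2[k] - 0.2, rt2[k] + 0.05)
        data[:, :, k] += response_amp * np.outer(-lateralized_topo, prof_r1)
        data[:, :, k] += response_amp * np.outer(lateralized_topo, prof_r2)

    ds = EpochedDataset(
        data=data,
        times=times,
        labels=labels,
        covariates={"rt1": rt1, "rt2": rt2},
    )
    truth = {
        "rt1": rt1,
        "rt2": rt2,
        "labels": labels.copy(),
        "early": {
            "topography": early_topo,
            "onset": early_onset,
            "durations": early_durations,
            "centers": early_onset + early_durations / 2.0,
        },
        "late": {
            "topography": late_topo,
            "latencies": late_latencies,
            "duration": late_duration,
            "centers": late_latencies + late_duration / 2.0,
        },
        "lateralized": {"topography": lateralized_topo, "amplitude": response_amp},
    }
    return ds, truth
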