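"""Objective functions: the map from a data slice plus labels/covariates
to one coefficient per channel.

An objective encodes the data-analysis question.  The canonical choice is
the difference between two condition means, evaluated independently at
each time point; windowed and whole-epoch-regression variants produce one
stationary filter instead.  Custom objectives are supported: anything
satisfying the :class:`ObjectiveSpec` contract (exactly ``n_channels``
finite coefficients, computed without the held-out trials) is accepted by
the transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import ConditionPair, EMSError, EpochedDataset

__all__ = [
    "ObjectiveSpec",
    "TemporalPredictor",
    "diff_of_means_objective",
    "windowed_diff_objective",
    "temporal_regression_objective",
    "temporal_difference_objective",
    "make_rt_predictor",
    "mean_difference",
    "windowed_difference",
    "temporal_regression",
    "temporal_difference",
    "resolve_window",
]

PER_TIMEPOINT = "per-timepoint"
WINDOWED = "windowed"
REGRESSION = "whole-epoch-regression"


def resolve_window(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Indices of samples with ``start_s <= t < end_s`` (half-open window)."""
    start, end = float(window[0]), float(window[1])
    idx = np.flatnonzero((times >= start) & (times < end))
    if idx.size == 0:
        raise EMSError(f"window [{start}, {end}) contains no samples")
    return idx


@dataclass
class ObjectiveSpec:
    """A named, parameterized objective function.

    ``evaluate`` receives, for ``kind="per-timepoint"``, a
    (channel x trial) slice and the matching labels; for the stationary
    kinds, the (channel x sample x trial) block, labels, original trial
    indices (to look up covariates/predictors) and the time vector.
    It must return exactly ``n_channels`` finite coefficients and, by
    construction of the transforms, never sees the held-out trial(s).
    """

    name: str
    kind: str
    evaluate: Callable[..., np.ndarray]
    params: dict = field(default_factory=dict)
    #: optional vectorized path: (channel x sample x trial, labels) -> channel x sample
    evaluate_all_samples: Callable[..., np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (PER_TIMEPOINT, WINDOWED, REGRESSION):
            raise EMSError(f"unknown objective kind {self.kind!r}")


@dataclass
class TemporalPredictor:
    """A trial x sample predictor matrix for regression objectives."""

    values: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise EMSError("predictor values must be a trial x sample matrix")
        if not np.isfinite(self.values).all():
            raise EMSError("predictor values must be finite")


# ---------------------------------------------------------------------------
# objective primitives (plain functions)
# ---------------------------------------------------------------------------

def diff_of_means_objective(
    slice_: np.ndarray, labels: np.ndarray, pair: ConditionPair
) -> np.ndarray:
    """Per-channel difference of class means at a single time point.

    ``slice_`` is channel x trial.  Returns mean over condition-A trials
    minus mean over condition-B trials, un-normalized (normalization to
    unit length is a separate step).
    """
    slice_ = np.asarray(slice_, dtype=float)
    mask_a, mask_b = pair.masks(labels)
    return slice_[:, mask_a].mean(axis=1) - slice_[:, mask_b].mean(axis=1)


def _diff_of_means_all_samples(
    data: np.ndarray, labels: np.ndarray, pair: ConditionPair
) -> np.ndarray:
    """Vectorized diff-of-means over every sample: channel x sample output."""
    mask_a, mask_b = pair.masks(labels)
    return data[:, :, mask_a].mean(axis=2) - data[:, :, mask_b].mean(axis=2)


def windowed_diff_objective(
    data: np.ndarray,
    labels: np.ndarray,
    times: np.ndarray,
    pair: ConditionPair,
    window: tuple[float, float],
) -> np.ndarray:
    """Difference of class means of the time-average over a window.

    Averages each channel over the window samples first, then subtracts
    the condition-B mean from the condition-A mean — the stationary
    template for following a fixed topography across the epoch.
    """
    idx = resolve_window(np.asarray(times, dtype=float), window)
    avg = np.asarray(data, dtype=float)[:, idx, :].mean(axis=1)  # channel x trial
    return diff_of_means_objective(avg, labels, pair)


def temporal_regression_objective(
    data: np.ndarray, predictor_values: np.ndarray
) -> np.ndarray:
    """Per-channel OLS slope of the data on a trial x sample predictor.

    Each channel's (trial x sample) values are flattened and regressed on
    the flattened predictor (single regressor plus intercept); the slope
    is the channel's coefficient.  One stationary filter results.
    """
    data = np.asarray(data, dtype=float)
    x = np.asarray(predictor_values, dtype=float)
    if x.shape != (data.shape[2], data.shape[1]):
        raise EMSError(
            "predictor shape does not match the data's (trial, sample) layout"
        )
    xf = x.T.ravel()  # matches data[ch].ravel() ordering (sample x trial)
    var = xf.var()
    if var == 0:
        raise EMSError("predictor is constant; regression slope undefined")
    xc = xf - xf.mean()
    # slope_ch = cov(x, y_ch) / var(x), vectorized over channels
    y = data.reshape(data.shape[0], -1)
    return (y @ xc) / (xc @ xc)


def temporal_difference_objective(
    data: np.ndarray,
    times: np.ndarray,
    window_a: tuple[float, float],
    window_b: tuple[float, float],
) -> np.ndarray:
    """Per-channel amplitude difference between two disjoint time windows.

    Mean over all trials and window-A samples minus the same for window B
    — e.g. readiness-potential-like buildup between ~500 ms and ~100 ms
    before movement onset, within a single condition.
    """
    times = np.asarray(times, dtype=float)
    idx_a = resolve_window(times, window_a)
    idx_b = resolve_window(times, window_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise EMSError("temporal_difference windows must be disjoint")
    data = np.asarray(data, dtype=float)
    return data[:, idx_a, :].mean(axis=(1, 2)) - data[:, idx_b, :].mean(axis=(1, 2))


def make_rt_predictor(
    rt1: np.ndarray,
    rt2: np.ndarray,
    times: np.ndarray,
    pre_s: float = 0.200,
    post_s: float = 0.050,
) -> TemporalPredictor:
    """Response-locked -1/+1 predictor from two per-trial reaction times.

    Samples within ``[rt1 - pre_s, rt1 + post_s]`` (inclusive bounds) are
    coded -1, samples within the same window around ``rt2`` are coded +1
    (the later response wins on overlap), all others 0.  A NaN reaction
    time leaves its window uncoded; two NaNs give an all-zero row.
    """
    if pre_s < 0 or post_s < 0:
        raise EMSError("pre_s and post_s must be non-negative")
    rt1 = np.asarray(rt1, dtype=float)
    rt2 = np.asarray(rt2, dtype=float)
    times = np.asarray(times, dtype=float)
    if rt1.shape != rt2.shape:
        raise EMSError("rt1 and rt2 must have the same length")
    values = np.zeros((rt1.size, times.size))
    for k in range(rt1.size):
        if np.isfinite(rt1[k]):
            values[k, (times >= rt1[k] - pre_s) & (times <= rt1[k] + post_s)] = -1.0
        if np.isfinite(rt2[k]):
            values[k, (times >= rt2[k] - pre_s) & (times <= rt2[k] + post_s)] = 1.0
    return TemporalPredictor(
        values,
        description=f"-1 around RT1, +1 around RT2 (pre {pre_s}s, post {post_s}s)",
    )


# ---------------------------------------------------------------------------
# ObjectiveSpec factories
# ---------------------------------------------------------------------------

def mean_difference(pair: ConditionPair) -> ObjectiveSpec:
    """Per-timepoint difference of condition means (the canonical objective)."""
    return ObjectiveSpec(
        name="mean_difference",
        kind=PER_TIMEPOINT,
        params={"pair": pair},
        evaluate=lambda slice_, labels: diff_of_means_objective(slice_, labels, pair),
        evaluate_all_samples=lambda data, labels: _diff_of_means_all_samples(
            data, labels, pair
        ),
    )


def windowed_difference(
    pair: ConditionPair, window: tuple[float, float]
) -> ObjectiveSpec:
    """Stationary template: window-averaged difference of condition means."""
    return ObjectiveSpec(
        name="windowed_difference",
        kind=WINDOWED,
        params={"pair": pair, "window": tuple(window)},
        evaluate=lambda data, labels, trial_idx, times: windowed_diff_objective(
            data, labels, times, pair, window
        ),
    )


def temporal_regression(predictor: TemporalPredictor) -> ObjectiveSpec:
    """Stationary filter of per-channel OLS slopes on a temporal predictor."""

    def _eval(data, labels, trial_idx, times):
        return temporal_regression_objective(data, predictor.values[trial_idx])

    return ObjectiveSpec(
        name="temporal_regression",
        kind=REGRESSION,
        params={"predictor": predictor},
        evaluate=_eval,
    )


def temporal_difference(
    window_a: tuple[float, float], window_b: tuple[float, float]
) -> ObjectiveSpec:
    """Stationary filter from the amplitude change between two windows."""
    return ObjectiveSpec(
        name="temporal_difference",
        kind=WINDOWED,
        params={"window_a": tuple(window_a), "window_b": tuple(window_b)},
        evaluate=lambda data, labels, trial_idx, times: temporal_difference_objective(
            data, times, window_a, window_b
        ),
    )
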