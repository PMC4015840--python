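"""Core containers for epoched multi-sensor recordings.

The package-wide convention for epoched data is a 3-D real array ordered
``channel x sample x trial``.  Per-trial condition labels, a uniformly
sampled time vector in seconds, per-channel sensor-group ids (e.g.
magnetometers vs. gradiometers) and optional per-trial behavioral
covariates (reaction times, NaN = no response) ride along with the array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EpochedDataset",
    "ConditionPair",
    "validate_dataset",
    "zscore_by_sensor_group",
    "balance_trial_counts",
]


class EMSError(ValueError):
    """Raised for contract violations anywhere in the package."""


@dataclass
class EpochedDataset:
    """Epoched multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples, n_trials)
        Sensor measurements in acquisition units (or z-score units after
        :func:`zscore_by_sensor_group`).
    times : ndarray, shape (n_samples,)
        Sample times in seconds; strictly increasing with a constant step.
    labels : ndarray of int, shape (n_trials,)
        Per-trial condition id.
    channel_names : sequence of str, optional
        One name per channel; auto-generated when omitted.
    channel_groups : ndarray of int, shape (n_channels,), optional
        Sensor-group id per channel (all zero when omitted).
    covariates : dict of str -> ndarray, optional
        Named per-trial real vectors; NaN encodes a missing value.
    units : dict of int -> str, optional
        Measurement unit per sensor group.
    """

    data: np.ndarray
    times: np.ndarray
    labels: np.ndarray
    channel_names: list[str] | None = None
    channel_groups: np.ndarray | None = None
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    units: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise EMSError(
                f"data must be 3-D (channel x sample x trial), got {self.data.ndim}-D"
            )
        m = self.data.shape[0]
        if self.channel_names is None:
            self.channel_names = [f"ch{i:03d}" for i in range(m)]
        else:
            self.channel_names = [str(c) for c in self.channel_names]
        if self.channel_groups is None:
            self.channel_groups = np.zeros(m, dtype=int)
        else:
            self.channel_groups = np.asarray(self.channel_groups, dtype=int)
        self.covariates = {
            k: np.asarray(v, dtype=float) for k, v in self.covariates.items()
        }
        if not self.units:
            self.units = {int(g): "au" for g in np.unique(self.channel_groups)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def sfreq(self) -> float:
        """Sampling rate in Hz, derived from the time step."""
        return 1.0 / float(self.times[1] - self.times[0])

    def validate(self) -> list[str]:
        return validate_dataset(self)

    def subset_trials(self, idx: np.ndarray) -> "EpochedDataset":
        """Return a copy restricted to the given trial indices (order kept)."""
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            data=self.data[:, :, idx],
            labels=self.labels[idx],
            covariates={k: v[idx] for k, v in self.covariates.items()},
            channel_names=list(self.channel_names),
            channel_groups=self.channel_groups.copy(),
            units=dict(self.units),
        )

    def copy(self) -> "EpochedDataset":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            labels=self.labels.copy(),
            channel_names=list(self.channel_names),
            channel_groups=self.channel_groups.copy(),
            covariates={k: v.copy() for k, v in self.covariates.items()},
            units=dict(self.units),
        )


@dataclass(frozen=True)
class ConditionPair:
    """An (effect, control) pair of condition labels, e.g. A vs. B."""

    label_a: int
    label_b: int

    def __post_init__(self) -> None:
        if self.label_a == self.label_b:
            raise EMSError("ConditionPair labels must differ")

    def masks(self, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        labels = np.asarray(labels)
        mask_a = labels == self.label_a
        mask_b = labels == self.label_b
        for name, mask in (("label_a", mask_a), ("label_b", mask_b)):
            if not mask.any():
                raise EMSError(
                    f"condition {getattr(self, name)} ({name}) has no trials"
                )
        return mask_a, mask_b


def validate_dataset(ds: EpochedDataset) -> list[str]:
    """Check every :class:`EpochedDataset` invariant.

    Returns a list of human-readable violation descriptions; an empty
    list means the dataset is well formed.  Never mutates the input.
    """
    violations: list[str] = []
    m, n, p = ds.data.shape
    if min(m, n, p) < 1:
        violations.append("data dimensions must all be strictly positive")
    if not np.isfinite(ds.data).all():
        violations.append("data finite: array contains NaN or infinite values")
    if ds.times.shape != (n,):
        violations.append(
            f"times length {ds.times.shape} inconsistent with n_samples={n}"
        )
    elif n > 1:
        dt = np.diff(ds.times)
        if not (dt > 0).all():
            violations.append("times must be strictly increasing")
        elif not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            violations.append("times must have a constant step (uniform sampling)")
    if not np.isfinite(ds.times).all():
        violations.append("times finite: vector contains NaN or infinite values")
    if ds.labels.shape != (p,):
        violations.append(
            f"labels length {ds.labels.shape} inconsistent with n_trials={p}"
        )
    if len(ds.channel_names) != m:
        violations.append("channel_names length inconsistent with n_channels")
    if ds.channel_groups.shape != (m,):
        violations.append("channel_groups length inconsistent with n_channels")
    for name, vec in ds.covariates.items():
        if vec.shape != (p,):
            violations.append(
                f"covariate '{name}' length inconsistent with n_trials={p}"
            )
    missing_units = set(np.unique(ds.channel_groups)) - set(ds.units)
    if missing_units:
        violations.append(f"units mapping missing group ids {sorted(missing_units)}")
    if ds.labels.size and np.unique(ds.labels).size < 1:
        violations.append("labels must take at least one distinct value")
    return violations


def zscore_by_sensor_group(ds: EpochedDataset) -> EpochedDataset:
    """Convert each sensor group to z-scores.

    Mean and standard deviation are computed over the entire
    (channels-in-group x samples x trials) block, separately per group —
    the normalization used to put magnetometers and gradiometers, whose
    units differ by an order of magnitude, on a common scale.  Uses the
    population standard deviation so each output block has unit variance
    exactly; the units mapping becomes ``"z-score"`` for every group.
    """
    out = ds.data.copy()
    units: dict[int, str] = {}
    for g in np.unique(ds.channel_groups):
        mask = ds.channel_groups == g
        block = ds.data[mask]
        mu = block.mean()
        sd = block.std()  # population SD over the whole block
        if sd == 0 or not np.isfinite(sd):
            raise EMSError(f"sensor group {g} has zero variance; cannot z-score")
        out[mask] = (block - mu) / sd
        units[int(g)] = "z-score"
    return replace(
        ds,
        data=out,
        units=units,
        channel_names=list(ds.channel_names),
        channel_groups=ds.channel_groups.copy(),
        covariates={k: v.copy() for k, v in ds.covariates.items()},
    )


def balance_trial_counts(
    labels: np.ndarray, pair: ConditionPair, seed: int | None = None
) -> np.ndarray:
    """Equalize trial counts of the two conditions by random subsampling.

    All trials of the smaller class are kept, and an equally sized subset
    of the larger class is drawn uniformly without replacement (seeded).
    The returned indices preserve the original trial order.
    """
    labels = np.asarray(labels)
    mask_a, mask_b = pair.masks(labels)
    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(mask_b)
    rng = np.random.default_rng(seed)
    if idx_a.size > idx_b.size:
        idx_a = rng.choice(idx_a, size=idx_b.size, replace=False)
    elif idx_b.size > idx_a.size:
        idx_b = rng.choice(idx_b, size=idx_a.size, replace=False)
    return np.sort(np.concatenate([idx_a, idx_b]))
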