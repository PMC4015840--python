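"""The EMS transform: per-timepoint matched spatial filters estimated on
held-out-trial complements, unit normalization, projection, the
stationary-template variant, optional noise-covariance whitening, and
filter-set diagnostics.

Every filter is set to unit Euclidean length before projection, so the
surrogate values it produces stay in the units of the data (microvolts,
femtotesla, z-scores, ...).  Cross-validation (leave-one-out by default)
guarantees that no trial is ever projected onto a filter its own data
influenced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import ConditionPair, EMSError, EpochedDataset
from .objectives import PER_TIMEPOINT, ObjectiveSpec

logger = logging.getLogger(__name__)

__all__ = [
    "CVScheme",
    "SpatialFilterSet",
    "SurrogateMatrix",
    "normalize_filter",
    "project_topography",
    "ems_transform",
    "stationary_transform",
    "whiten_filter",
    "filter_similarity",
]

#: relative tolerance classifying a filter as degenerate (all-zero output)
DEGENERACY_RTOL = 1e-12


@dataclass
class CVScheme:
    """Cross-validation scheme assigning every trial to exactly one fold.

    kinds: ``"loo"`` (one fold per trial, the default), ``"loopc"``
    (one held-out trial per condition per fold; requires equal class
    counts), ``"kfold"`` (label-stratified, seeded), ``"loso"``
    (leave-one-subject-out; per-subject class means are pre-computed
    before differencing across the retained subjects).
    """

    kind: str = "loo"
    k: int | None = None
    subject_ids: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("loo", "loopc", "kfold", "loso"):
            raise EMSError(f"unknown CV scheme kind {self.kind!r}")
        if self.kind == "kfold" and (self.k is None or self.k < 2):
            raise EMSError("kfold scheme requires k >= 2")
        if self.kind == "loso" and self.subject_ids is None:
            raise EMSError("loso scheme requires subject_ids")

    def folds(
        self, labels: np.ndarray, pair: ConditionPair | None = None
    ) -> list[np.ndarray]:
        """Held-out trial index sets, one array per fold."""
        labels = np.asarray(labels)
        p = labels.size
        if self.kind == "loo":
            return [np.array([k]) for k in range(p)]
        if self.kind == "loopc":
            if pair is None:
                raise EMSError("loopc scheme requires a ConditionPair")
            idx_a = np.flatnonzero(labels == pair.label_a)
            idx_b = np.flatnonzero(labels == pair.label_b)
            if idx_a.size != idx_b.size:
                raise EMSError(
                    "loopc requires equal trial counts per condition; "
                    "use balance_trial_counts first"
                )
            rng = np.random.default_rng(self.seed)
            idx_a = rng.permutation(idx_a)
            idx_b = rng.permutation(idx_b)
            return [np.sort(np.array([a, b])) for a, b in zip(idx_a, idx_b)]
        if self.kind == "kfold":
            from sklearn.model_selection import StratifiedKFold

            skf = StratifiedKFold(
                n_splits=self.k, shuffle=True, random_state=self.seed
            )
            return [test for _, test in skf.split(np.zeros(p), labels)]
        # loso
        subject_ids = np.asarray(self.subject_ids)
        if subject_ids.size != p:
            raise EMSError("subject_ids length must equal n_trials")
        return [
            np.flatnonzero(subject_ids == s) for s in np.unique(subject_ids)
        ]

    def describe(self) -> str:
        if self.kind == "kfold":
            return f"kfold(k={self.k}, seed={self.seed})"
        if self.kind == "loopc":
            return f"loopc(seed={self.seed})"
        return self.kind


@dataclass
class SpatialFilterSet:
    """Unit-norm spatial filters indexed by (channel, sample, fold).

    For the stationary variant the sample axis has length 1.  The
    ``degenerate`` mask flags (sample, fold) filters whose un-normalized
    coefficients were numerically zero; those filters are all-zero.
    """

    filters: np.ndarray  # channel x sample x fold
    folds: list[np.ndarray]
    scheme: str
    normalized: bool = True
    degenerate: np.ndarray | None = None  # sample x fold
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(self.filters.shape[1:], dtype=bool)

    @property
    def n_folds(self) -> int:
        return self.filters.shape[2]

    def fold_average(self) -> np.ndarray:
        """Mean filter over folds, channel x sample."""
        return self.filters.mean(axis=2)


@dataclass
class SurrogateMatrix:
    """Trial x sample surrogate time courses, in the data's units."""

    values: np.ndarray
    labels: np.ndarray
    degenerate: np.ndarray | None = None  # trial x sample
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(self.values.shape, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def normalize_filter(
    d: np.ndarray, slice_norm: float | None = None
) -> tuple[np.ndarray, bool]:
    """Scale a coefficient vector to unit Euclidean length.

    Degenerate inputs (norm below ``1e-12 * max(1, slice_norm)``) return
    an all-zero vector and ``True`` — they arise legitimately under exact
    nulls and must not abort a whole transform.
    """
    d = np.asarray(d, dtype=float)
    if not np.isfinite(d).all():
        raise EMSError("filter coefficients must be finite")
    nrm = float(np.linalg.norm(d))
    ref = max(1.0, slice_norm) if slice_norm is not None else 1.0
    if nrm < DEGENERACY_RTOL * ref:
        return np.zeros_like(d), True
    return d / nrm, False


def project_topography(x: np.ndarray, w_hat: np.ndarray) -> float:
    """Dot product of an observed topography with a unit-norm filter.

    Returns a single scalar in the units of ``x`` (unit filter norm
    preserves measurement units).
    """
    x = np.asarray(x, dtype=float)
    w_hat = np.asarray(w_hat, dtype=float)
    if x.shape != w_hat.shape:
        raise EMSError("topography and filter must have the same length")
    return float(x @ w_hat)


def _check_units(ds: EpochedDataset) -> None:
    present = np.unique(ds.channel_groups)
    unit_set = {ds.units.get(int(g), "au") for g in present}
    if len(unit_set) > 1:
        raise EMSError(
            f"dataset mixes sensor groups with different units {sorted(unit_set)}; "
            "convert to z-scores (zscore_by_sensor_group) or filter the groups "
            "separately before transforming"
        )


def _evaluated(coeffs: np.ndarray, m: int) -> np.ndarray:
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (m,):
        raise EMSError(
            f"objective returned {coeffs.shape}, expected ({m},) — one "
            "coefficient per channel"
        )
    if not np.isfinite(coeffs).all():
        raise EMSError("objective returned non-finite coefficients")
    return coeffs


def _check_loo_class_counts(
    ds: EpochedDataset, objective: ObjectiveSpec, scheme: CVScheme
) -> None:
    pair = objective.params.get("pair")
    if pair is None:
        return
    mask_a, mask_b = pair.masks(ds.labels)
    if scheme.kind in ("loo", "loopc") and min(mask_a.sum(), mask_b.sum()) < 2:
        raise EMSError(
            "need at least 2 trials per condition for leave-one-out "
            "with a difference-of-means objective"
        )


def ems_transform(
    ds: EpochedDataset, objective: ObjectiveSpec, scheme: CVScheme | None = None
) -> tuple[SurrogateMatrix, SpatialFilterSet]:
    """Effect-matched spatial filtering of an epoched dataset.

    For every cross-validation fold and every time sample, the objective
    is evaluated on all trials *not* in the fold, the resulting
    coefficient vector is normalized to unit length, and each held-out
    trial's topography at that sample is projected onto it.  Returns the
    trial x sample surrogate matrix and the full filter set.
    """
    scheme = scheme or CVScheme("loo")
    if objective.kind != PER_TIMEPOINT:
        raise EMSError(
            f"ems_transform requires a per-timepoint objective, got kind="
            f"{objective.kind!r}; use stationary_transform"
        )
    problems = ds.validate()
    if problems:
        raise EMSError("invalid dataset: " + "; ".join(problems))
    _check_units(ds)
    _check_loo_class_counts(ds, objective, scheme)

    m, n, p = ds.data.shape
    folds = scheme.folds(ds.labels, objective.params.get("pair"))
    filters = np.zeros((m, n, len(folds)))
    degen_f = np.zeros((n, len(folds)), dtype=bool)
    values = np.zeros((p, n))
    degen_s = np.zeros((p, n), dtype=bool)
    X = ds.data

    all_idx = np.arange(p)
    for fk, held in enumerate(folds):
        keep = np.setdiff1d(all_idx, held, assume_unique=False)
        if keep.size == 0:
            raise EMSError("a fold holds out every trial; nothing left to fit")
        sub = X[:, :, keep]
        lab = ds.labels[keep]
        if scheme.kind == "loso" and objective.name == "mean_difference":
            # per-subject class means first, then averaged across subjects
            D = _loso_mean_difference(
                sub, lab, np.asarray(scheme.subject_ids)[keep],
                objective.params["pair"],
            )
        elif objective.evaluate_all_samples is not None:
            D = _evaluated_matrix(objective.evaluate_all_samples(sub, lab), m, n)
        else:
            D = np.empty((m, n))
            for j in range(n):
                D[:, j] = _evaluated(objective.evaluate(sub[:, j, :], lab), m)
        norms = np.linalg.norm(D, axis=0)
        refs = np.maximum(1.0, np.linalg.norm(sub, axis=(0, 2)))
        bad = norms < DEGENERACY_RTOL * refs
        D_hat = np.where(bad[None, :], 0.0, D / np.where(bad, 1.0, norms)[None, :])
        filters[:, :, fk] = D_hat
        degen_f[:, fk] = bad
        # project each held-out trial sample-by-sample
        values[held, :] = np.einsum("ij,ijt->tj", D_hat, X[:, :, held])
        degen_s[held, :] = bad[None, :]

    n_degen = int(degen_f.sum())
    if n_degen:
        logger.info("ems_transform: %d degenerate (zero-norm) filters", n_degen)
    fs = SpatialFilterSet(
        filters=filters,
        folds=folds,
        scheme=scheme.describe(),
        normalized=True,
        degenerate=degen_f,
        times=ds.times.copy(),
    )
    sm = SurrogateMatrix(
        values=values,
        labels=ds.labels.copy(),
        degenerate=degen_s,
        times=ds.times.copy(),
    )
    return sm, fs


def _loso_mean_difference(
    data: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
    pair: ConditionPair,
) -> np.ndarray:
    """Across-subject mean of per-subject class-mean differences."""
    diffs = []
    for s in np.unique(subjects):
        sel = subjects == s
        mask_a = sel & (labels == pair.label_a)
        mask_b = sel & (labels == pair.label_b)
        if not mask_a.any() or not mask_b.any():
            raise EMSError(
                f"subject {s} lacks trials of one condition; cannot form "
                "its class-mean difference"
            )
        diffs.append(
            data[:, :, mask_a].mean(axis=2) - data[:, :, mask_b].mean(axis=2)
        )
    return np.mean(diffs, axis=0)


def _evaluated_matrix(D: np.ndarray, m: int, n: int) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.shape != (m, n):
        raise EMSError(
            f"vectorized objective returned {D.shape}, expected ({m}, {n})"
        )
    if not np.isfinite(D).all():
        raise EMSError("objective returned non-finite coefficients")
    return D


def stationary_transform(
    ds: EpochedDataset, objective: ObjectiveSpec, scheme: CVScheme | None = None
) -> tuple[SurrogateMatrix, SpatialFilterSet]:
    """EMS filtering with a single stationary template per fold.

    The objective (windowed difference, temporal difference, or temporal
    regression) produces one filter per fold; each held-out trial's full
    channel x sample matrix is projected onto that same filter at every
    sample, exposing the time course — and possible re-appearance — of a
    fixed topography.
    """
    scheme = scheme or CVScheme("loo")
    if objective.kind == PER_TIMEPOINT:
        raise EMSError(
            "stationary_transform requires a windowed or regression objective; "
            "use ems_transform for per-timepoint objectives"
        )
    problems = ds.validate()
    if problems:
        raise EMSError("invalid dataset: " + "; ".join(problems))
    _check_units(ds)
    _check_loo_class_counts(ds, objective, scheme)

    m, n, p = ds.data.shape
    folds = scheme.folds(ds.labels, objective.params.get("pair"))
    filters = np.zeros((m, 1, len(folds)))
    degen_f = np.zeros((1, len(folds)), dtype=bool)
    values = np.zeros((p, n))
    degen_s = np.zeros((p, n), dtype=bool)
    all_idx = np.arange(p)
    for fk, held in enumerate(folds):
        keep = np.setdiff1d(all_idx, held)
        if keep.size == 0:
            raise EMSError("a fold holds out every trial; nothing left to fit")
        d = _evaluated(
            objective.evaluate(ds.data[:, :, keep], ds.labels[keep], keep, ds.times),
            m,
        )
        w_hat, bad = normalize_filter(d, float(np.linalg.norm(ds.data[:, :, keep])))
        filters[:, 0, fk] = w_hat
        degen_f[0, fk] = bad
        values[held, :] = np.einsum("i,ijt->tj", w_hat, ds.data[:, :, held])
        degen_s[held, :] = bad

    fs = SpatialFilterSet(
        filters=filters,
        folds=folds,
        scheme=scheme.describe(),
        normalized=True,
        degenerate=degen_f,
        times=ds.times.copy(),
    )
    sm = SurrogateMatrix(
        values=values,
        labels=ds.labels.copy(),
        degenerate=degen_s,
        times=ds.times.copy(),
    )
    return sm, fs


def whiten_filter(
    d: np.ndarray, noise_cov: np.ndarray, shrinkage: float = 0.0
) -> np.ndarray:
    """Multiply a filter by a (shrunk) inverse noise covariance.

    Fisher-discriminant-style weighting that down-weights noisy channels:
    returns ``((1 - s) * Sigma + s * mean_diag * I)^{-1} d``.  The caller
    normalizes afterwards.  Off by default in every pipeline — the plain
    matched filter keeps the weight vector interpretable as a topography.
    """
    d = np.asarray(d, dtype=float)
    sigma = np.asarray(noise_cov, dtype=float)
    if not (0.0 <= shrinkage <= 1.0):
        raise EMSError("shrinkage must lie in [0, 1]")
    if sigma.shape != (d.size, d.size):
        raise EMSError("noise covariance must be channel x channel")
    if not np.isfinite(sigma).all():
        raise EMSError("noise covariance must be finite")
    if not np.allclose(sigma, sigma.T, atol=1e-10 * max(1.0, float(np.abs(sigma).max()))):
        raise EMSError("noise covariance must be symmetric")
    target = np.eye(d.size) * float(np.trace(sigma)) / d.size
    reg = (1.0 - shrinkage) * sigma + shrinkage * target
    try:
        from scipy.linalg import solve

        return solve(reg, d, assume_a="pos")
    except Exception as exc:  # singular / not PD
        raise EMSError(
            "regularized noise covariance is singular; increase shrinkage"
        ) from exc


def filter_similarity(fs: SpatialFilterSet) -> np.ndarray:
    """Sample x sample Pearson correlation of fold-averaged filters.

    Reveals stable topographical regimes (blocks of high correlation) and
    transitions between them across the epoch.  Samples whose filters are
    degenerate in every fold yield NaN rows/columns.
    """
    if not fs.normalized:
        raise EMSError("filter_similarity requires a normalized filter set")
    avg = fs.fold_average()  # channel x sample
    n = avg.shape[1]
    centered = avg - avg.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    sim = np.full((n, n), np.nan)
    good = norms > 0
    if good.any():
        c = centered[:, good] / norms[good]
        sim[np.ix_(good, good)] = c.T @ c
    return sim
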