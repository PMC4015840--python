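"""Model-style front end: an :class:`EMS` model built from an epoched
dataset whose :meth:`EMS.fit` returns an :class:`EMSResults` object
carrying the surrogate matrix, the filter set, the effect time course
with its confidence band, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np

from .data import ConditionPair, EMSError, EpochedDataset, zscore_by_sensor_group
from .objectives import PER_TIMEPOINT, ObjectiveSpec, mean_difference
from .core import (
    CVScheme,
    SpatialFilterSet,
    SurrogateMatrix,
    ems_transform,
    filter_similarity,
    stationary_transform,
)
from .evaluation import (
    DecodingResult,
    EffectTimeCourse,
    SNRReport,
    effect_time_course,
    estimate_snr,
    nested_gnb_decode,
)

__all__ = ["EMS", "EMSResults"]


class EMS:
    """Effect-matched spatial filtering model.

    Parameters
    ----------
    dataset : EpochedDataset
        Epoched recording (channel x sample x trial).
    pair : ConditionPair, optional
        Effect/control condition pair; required for the default
        difference-of-means objective.
    objective : ObjectiveSpec, optional
        Alternative objective; defaults to the per-timepoint difference
        of condition means for ``pair``.
    cv : CVScheme, optional
        Cross-validation scheme (leave-one-out by default).
    zscore : bool
        Z-score each sensor group over the entire dataset before
        filtering (required when sensor groups have different units).
    """

    def __init__(
        self,
        dataset: EpochedDataset,
        pair: ConditionPair | None = None,
        objective: ObjectiveSpec | None = None,
        cv: CVScheme | None = None,
        zscore: bool = False,
    ) -> None:
        if objective is None:
            if pair is None:
                raise EMSError("provide a ConditionPair or an explicit objective")
            objective = mean_difference(pair)
        self.dataset = zscore_by_sensor_group(dataset) if zscore else dataset
        self.pair = pair or objective.params.get("pair")
        self.objective = objective
        self.cv = cv or CVScheme("loo")

    @classmethod
    def from_arrays(
        cls,
        data: np.ndarray,
        times: np.ndarray,
        labels: np.ndarray,
        pair: ConditionPair | None = None,
        **kwargs,
    ) -> "EMS":
        ds = EpochedDataset(data=data, times=times, labels=labels)
        if pair is None:
            uniq = np.unique(ds.labels)
            if uniq.size == 2:
                pair = ConditionPair(int(uniq[0]), int(uniq[1]))
        return cls(ds, pair=pair, **kwargs)

    def fit(self) -> "EMSResults":
        """Run the (cross-validated) transform and package the results."""
        if self.objective.kind == PER_TIMEPOINT:
            surrogates, filters = ems_transform(self.dataset, self.objective, self.cv)
        else:
            surrogates, filters = stationary_transform(
                self.dataset, self.objective, self.cv
            )
        return EMSResults(self, surrogates, filters)


class EMSResults:
    """Results of an EMS fit.

    Attributes
    ----------
    surrogates : SurrogateMatrix
        Trial x sample surrogate time courses in the data's units.
    filters : SpatialFilterSet
        Unit-norm spatial filters, channel x sample x fold.
    """

    def __init__(
        self,
        model: EMS,
        surrogates: SurrogateMatrix,
        filters: SpatialFilterSet,
    ) -> None:
        self.model = model
        self.surrogates = surrogates
        self.filters = filters

    # -- derived quantities --------------------------------------------
    def effect_course(self, conf_level: float = 0.99) -> EffectTimeCourse:
        """Condition-difference course of the surrogates with a t band."""
        if self.model.pair is None:
            raise EMSError("effect course requires a ConditionPair")
        return effect_time_course(self.surrogates, self.model.pair, conf_level)

    def snr(
        self,
        signal_window: tuple[float, float],
        noise_window: tuple[float, float],
    ) -> SNRReport:
        course = self.effect_course().difference
        return estimate_snr(
            course, self.model.dataset.times, signal_window, noise_window
        )

    def decode(self, smooth_s: float = 0.050, seed: int | None = None) -> DecodingResult:
        """Nested EMS + Gaussian naive-Bayes decoding of the pair."""
        return nested_gnb_decode(
            self.model.dataset, self.model.pair, self.model.objective,
            smooth_s=smooth_s, seed=seed,
        )

    def filter_similarity(self) -> np.ndarray:
        return filter_similarity(self.filters)

    @property
    def n_degenerate_filters(self) -> int:
        return int(self.filters.degenerate.sum())

    # -- presentation ---------------------------------------------------
    def summary(self, conf_level: float = 0.99) -> str:
        ds = self.model.dataset
        lines = [
            "EMS filtering results",
            "=" * 54,
            f"{'channels':<28}{ds.n_channels}",
            f"{'samples':<28}{ds.n_samples}",
            f"{'trials':<28}{ds.n_trials}",
            f"{'objective':<28}{self.model.objective.name}",
            f"{'cross-validation':<28}{self.filters.scheme}",
            f"{'folds':<28}{self.filters.n_folds}",
            f"{'degenerate filters':<28}{self.n_degenerate_filters}",
        ]
        if self.model.pair is not None:
            course = self.effect_course(conf_level)
            j = int(np.argmax(np.abs(course.difference)))
            lines += [
                f"{'conditions (A vs B)':<28}"
                f"{self.model.pair.label_a} vs {self.model.pair.label_b}",
                f"{'peak |effect|':<28}{course.difference[j]:+.4g}",
                f"{'peak latency (s)':<28}{ds.times[j]:.4f}",
                f"{'ci half-width at peak':<28}{course.half_width[j]:.4g} "
                f"({int(conf_level * 100)}%)",
            ]
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_effect(self, ax=None, conf_level: float = 0.99):
        """Plot the effect time course with its confidence band."""
        import matplotlib.pyplot as plt

        course = self.effect_course(conf_level)
        if ax is None:
            _, ax = plt.subplots()
        t = self.model.dataset.times
        ax.plot(t, course.difference, color="C0", label="effect (A - B)")
        ax.fill_between(
            t,
            course.difference - course.half_width,
            course.difference + course.half_width,
            alpha=0.3,
            color="C0",
            label=f"{int(conf_level * 100)}% band",
        )
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("surrogate difference (data units)")
        ax.legend()
        return ax
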