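"""Evaluation: per-stage accuracy, the averaged accuracy, and the W sweep.

The averaged classification accuracy is the *unweighted* mean of the five
per-stage accuracies (confusion-matrix diagonal over row sum), the
convention under which the published per-stage values 89.17/86.67/88.33/
87.50/84.17 % average to 87.17 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import fit_centroids, label_centroids, stage_mean_centroids, classify_session
from .errors import AlignmentError, InvalidParameterError
from .processing import FeatureVector
from .scaling import ScalingConfig, apply_scaling, fit_voltage_reference
from .stages import STAGE_ORDER, SleepStage


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion matrix (true stage x predicted stage) and its accuracies."""

    confusion: np.ndarray
    stages: tuple[SleepStage, ...] = STAGE_ORDER

    def __post_init__(self):
        c = np.asarray(self.confusion, dtype=int)
        k = len(self.stages)
        if c.shape != (k, k):
            raise InvalidParameterError(f"confusion must be {k}x{k}, got {c.shape}")
        if np.any(c < 0):
            raise InvalidParameterError("confusion counts must be >= 0")
        object.__setattr__(self, "confusion", c)

    @classmethod
    def from_labels(cls, predicted: Sequence[SleepStage],
                    truth: Sequence[SleepStage]) -> "ClassificationReport":
        if len(predicted) != len(truth):
            raise AlignmentError(
                f"{len(predicted)} predictions vs {len(truth)} true windows")
        k = len(STAGE_ORDER)
        c = np.zeros((k, k), dtype=int)
        for p, t in zip(predicted, truth):
            c[int(t), int(p)] += 1
        return cls(c)

    @property
    def n_per_stage(self) -> dict[SleepStage, int]:
        return {s: int(n) for s, n in zip(self.stages, self.confusion.sum(axis=1))}

    @property
    def per_stage_accuracy(self) -> dict[SleepStage, float]:
        """Diagonal over row sum; stages with no windows get NaN."""
        rows = self.confusion.sum(axis=1)
        diag = np.diag(self.confusion)
        return {s: (diag[i] / rows[i] if rows[i] else float("nan"))
                for i, s in enumerate(self.stages)}

    @property
    def averaged_accuracy(self) -> float:
        """Unweighted mean of the per-stage accuracies (stages with data)."""
        vals = [a for a in self.per_stage_accuracy.values() if not np.isnan(a)]
        return float(np.mean(vals))

    def to_frame(self) -> pd.DataFrame:
        names = [s.name for s in self.stages]
        return pd.DataFrame(self.confusion, index=pd.Index(names, name="true"),
                            columns=pd.Index(names, name="predicted"))


def evaluate(predicted: Sequence[SleepStage],
             truth: Sequence[SleepStage]) -> ClassificationReport:
    """Tally aligned predicted/true hypnograms into a report."""
    return ClassificationReport.from_labels(predicted, truth)


@dataclass(frozen=True)
class SweepResult:
    """Averaged accuracy at each tried weight value W."""

    weights: tuple[float, ...]
    accuracy_at_W: tuple[float, ...]

    def __post_init__(self):
        if len(self.weights) != len(self.accuracy_at_W):
            raise InvalidParameterError("weights and accuracies must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"W": self.weights, "accuracy": self.accuracy_at_W})


def fit_and_classify(train: Sequence[FeatureVector],
                     test: Sequence[FeatureVector],
                     weight_W: float = 0.1, k: int = 5, seed: int = 0,
                     n_init: int = 10, mode: str = "kmeans",
                     strict_labels: bool = False):
    """Scale on the training set, fit/label centroids, classify the test set.

    Returns (report, centroid set).  ``mode`` selects the unsupervised
    k-means fit with majority labeling ("kmeans") or per-stage mean
    centroids ("supervised").
    """
    if any(p.stage_label is None for p in train):
        raise InvalidParameterError("training features must be labeled")
    config = ScalingConfig(weight_W=weight_W,
                           voltage_reference=fit_voltage_reference(train))
    strain = apply_scaling(train, config)
    stest = apply_scaling(test, config)
    if mode == "kmeans":
        cset = fit_centroids(strain, k=k, seed=seed, n_init=n_init, scaling=config)
        cset = label_centroids(cset, strain, strict=strict_labels)
    elif mode == "supervised":
        cset = stage_mean_centroids(strain, scaling=config)
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    predicted = classify_session(stest, cset)
    truth = [p.stage_label for p in test]
    if any(t is None for t in truth):
        raise InvalidParameterError("test features must be labeled to evaluate")
    return evaluate(predicted, truth), cset


def weight_sweep(train: Sequence[FeatureVector], test: Sequence[FeatureVector],
                 weights: Sequence[float], k: int = 5, seed: int = 0,
                 n_init: int = 10, mode: str = "kmeans") -> SweepResult:
    """Refit and re-evaluate the whole classifier at each weight value W."""
    if not weights:
        raise InvalidParameterError("weight list must not be empty")
    accs = []
    for w in weights:
        report, _ = fit_and_classify(train, test, weight_W=w, k=k, seed=seed,
                                     n_init=n_init, mode=mode)
        accs.append(report.averaged_accuracy)
    return SweepResult(tuple(float(w) for w in weights), tuple(accs))


def relative_difference_report(
        voltages_by_session: Mapping[str, Mapping[SleepStage, float]]
) -> pd.DataFrame:
    """Between-session voltage differences, raw vs relative, per stage.

    ``voltages_by_session`` maps a session key (e.g. "day1") to per-stage
    output voltages.  The relative value divides by the global maximum over
    all sessions and stages; since that maximum exceeds 1 V for this sensor,
    relative differences are no larger than raw ones.  Differences are the
    mean absolute pairwise difference across sessions.
    """
    if len(voltages_by_session) < 2:
        raise InvalidParameterError("need at least 2 sessions to compare")
    stages = set()
    for per_stage in voltages_by_session.values():
        stages.update(per_stage)
    ref = max(v for per_stage in voltages_by_session.values()
              for v in per_stage.values())
    if ref <= 0:
        raise InvalidParameterError("all voltages are zero")
    rows = []
    for stage in sorted(stages):
        vals = [per_stage[stage] for per_stage in voltages_by_session.values()
                if stage in per_stage]
        if len(vals) < 2:
            raise InvalidParameterError(
                f"stage {stage.name}: need >= 2 repeated measurements")
        diffs = [abs(a - b) for i, a in enumerate(vals) for b in vals[i + 1:]]
        raw = float(np.mean(diffs))
        rows.append({"stage": stage.name, "raw_difference": raw,
                     "relative_difference": raw / ref})
    return pd.DataFrame(rows).set_index("stage")
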