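"""Multilabel imbalance quantification.

Two standard measures drive the oversampling decisions in this package:

* **IRL** (imbalance ratio per label): the count of the most frequent label
  divided by the count of each label.  The majority label scores exactly 1;
  rarer labels score higher.
* **SCUMBLE** (Score of ConcUrrence among iMBalanced LabEls): a per-instance
  score in [0, 1] measuring how strongly majority and minority labels
  co-occur, averaged over the dataset.  A dataset value at or below 0.1
  indicates low concurrence, the regime in which minority oversampling is
  expected to help rather than inject label noise.

Labels are then partitioned relative to the mean and median of the IRL
distribution: *minority* (IRL > mean), *medium* (median < IRL < mean) and
*majority* (the rest).  A macro-F1 utility rounds out the module for
evaluating multilabel predictions per class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMatrix",
    "ImbalanceProfile",
    "ScumbleReport",
    "compute_irl",
    "categorize_classes",
    "compute_scumble",
    "build_profile",
    "macro_f1",
    "binarize",
    "SCUMBLE_BENEFIT_THRESHOLD",
]

#: Dataset-level SCUMBLE at or below this value indicates the dataset is
#: expected to benefit from minority oversampling.
SCUMBLE_BENEFIT_THRESHOLD = 0.1

MAJORITY = "majority"
MEDIUM = "medium"
MINORITY = "minority"


@dataclass(frozen=True)
class LabelMatrix:
    """Binary instances x labels table.

    Parameters
    ----------
    entries
        Array of shape ``(n_instances, n_labels)`` with 0/1 entries.
    label_names
        Ordered label identifiers, one per column.
    instance_ids
        Ordered sample identifiers, one per row.
    """

    entries: np.ndarray
    label_names: tuple[str, ...]
    instance_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.int8)
        if entries.ndim != 2 or entries.size == 0:
            raise ValueError("label matrix must be 2-D and non-empty")
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("label matrix entries must be 0 or 1")
        if entries.shape[1] != len(self.label_names):
            raise ValueError("label_names length must match the number of columns")
        if entries.shape[0] != len(self.instance_ids):
            raise ValueError("instance_ids length must match the number of rows")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "label_names", tuple(str(n) for n in self.label_names))
        object.__setattr__(self, "instance_ids", tuple(str(i) for i in self.instance_ids))

    @property
    def n_instances(self) -> int:
        return self.entries.shape[0]

    @property
    def n_labels(self) -> int:
        return self.entries.shape[1]

    def label_counts(self) -> np.ndarray:
        """Positive-instance count per label column."""
        return self.entries.sum(axis=0)

    def label_set(self, instance_id: str) -> frozenset[str]:
        row = self.entries[self.instance_ids.index(instance_id)]
        return frozenset(n for n, v in zip(self.label_names, row) if v)


@dataclass(frozen=True)
class ImbalanceProfile:
    """Per-label IRL values plus the majority/medium/minority partition."""

    irl: Mapping[str, float]
    irl_mean: float
    irl_median: float
    categories: Mapping[str, str]

    def labels_in(self, category: str) -> list[str]:
        return [name for name, cat in self.categories.items() if cat == category]

    @property
    def minority(self) -> list[str]:
        return self.labels_in(MINORITY)

    @property
    def medium(self) -> list[str]:
        return self.labels_in(MEDIUM)

    @property
    def majority(self) -> list[str]:
        return self.labels_in(MAJORITY)


@dataclass(frozen=True)
class ScumbleReport:
    """SCUMBLE per instance and for the dataset, with the benefit decision."""

    per_instance: np.ndarray
    dataset_value: float
    benefits_from_resampling: bool
    excluded_instances: tuple[str, ...] = field(default_factory=tuple)


def compute_irl(labels: LabelMatrix) -> dict[str, float]:
    """Imbalance ratio per label: max label count over each label's count.

    Raises
    ------
    ValueError
        If any label column has no positive instance (the ratio is
        undefined); the error names the offending labels.
    """
    counts = labels.label_counts()
    zero = [labels.label_names[j] for j in np.flatnonzero(counts == 0)]
    if zero:
        raise ValueError(
            f"IRL undefined: label(s) with zero positive instances: {zero}"
        )
    max_count = counts.max()
    return {
        name: float(max_count) / float(c)
        for name, c in zip(labels.label_names, counts)
    }


def categorize_classes(irl: Mapping[str, float]) -> dict[str, str]:
    """Partition labels into majority / medium / minority by IRL.

    Minority: IRL strictly above the mean of all IRL values.
    Medium:   median < IRL < mean (both strict).
    Majority: everything else (IRL <= median, and any value tied with the
    mean or the median falls here because the inequalities are strict).
    """
    if not irl:
        raise ValueError("empty IRL map")
    values = np.array(list(irl.values()), dtype=float)
    mean = float(values.mean())
    median = float(np.median(values))
    out: dict[str, str] = {}
    for name, v in irl.items():
        if v > mean:
            out[name] = MINORITY
        elif median < v < mean:
            out[name] = MEDIUM
        else:
            out[name] = MAJORITY
    return out


def build_profile(labels: LabelMatrix) -> ImbalanceProfile:
    """Convenience: IRL map, its mean/median and the class partition."""
    irl = compute_irl(labels)
    values = np.array(list(irl.values()), dtype=float)
    return ImbalanceProfile(
        irl=irl,
        irl_mean=float(values.mean()),
        irl_median=float(np.median(values)),
        categories=categorize_classes(irl),
    )


def compute_scumble(labels: LabelMatrix) -> ScumbleReport:
    """SCUMBLE concurrence score per instance and for the dataset.

    For an instance with active labels of ratios ``IRL_1..IRL_k`` the score
    is ``1 - geometric_mean(IRL) / arithmetic_mean(IRL)``, i.e. 0 when the
    active labels are equally (im)balanced and approaching 1 when extreme
    majority and minority labels coexist.  The geometric mean runs over the
    instance's *active* labels only, so single-label instances score 0.

    Instances with empty label sets have no defined score; they are excluded
    from the dataset mean with a logged warning.  A dataset where every
    instance is empty is an error.
    """
    irl_map = compute_irl(labels)
    irl = np.array([irl_map[n] for n in labels.label_names], dtype=float)
    active = labels.entries.astype(bool)
    k = active.sum(axis=1)

    empty = k == 0
    if empty.all():
        raise ValueError("SCUMBLE undefined: every instance has an empty label set")
    excluded: tuple[str, ...] = ()
    if empty.any():
        excluded = tuple(np.array(labels.instance_ids)[empty])
        logger.warning(
            "excluding %d instance(s) with empty label sets from SCUMBLE: %s",
            len(excluded),
            list(excluded[:5]),
        )

    keep = ~empty
    act = active[keep]
    kk = k[keep].astype(float)
    # geometric mean over active labels: masked product ** (1/k)
    prod = np.where(act, irl[np.newaxis, :], 1.0).prod(axis=1)
    geo = prod ** (1.0 / kk)
    arith = (act * irl[np.newaxis, :]).sum(axis=1) / kk
    per_instance = np.clip(1.0 - geo / arith, 0.0, 1.0)

    dataset_value = float(per_instance.mean())
    return ScumbleReport(
        per_instance=per_instance,
        dataset_value=dataset_value,
        benefits_from_resampling=dataset_value <= SCUMBLE_BENEFIT_THRESHOLD,
        excluded_instances=excluded,
    )


def binarize(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability matrix into a 0/1 prediction matrix."""
    return (np.asarray(probabilities, dtype=float) >= threshold).astype(np.int8)


def macro_f1(
    predicted: np.ndarray,
    truth: np.ndarray,
    label_names: Sequence[str] | None = None,
) -> tuple[float, dict[str, float]]:
    """Macro-averaged F1: the unweighted mean of per-label F1 scores.

    Per label, ``F1 = 2 TP / (2 TP + FP + FN)``; a label with no positives
    in either matrix (denominator zero) contributes 0, keeping the macro
    mean defined.

    Returns the macro value and a per-label F1 map.
    """
    predicted = np.asarray(predicted, dtype=np.int8)
    truth = np.asarray(truth, dtype=np.int8)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs truth {truth.shape}"
        )
    if label_names is None:
        label_names = [str(j) for j in range(truth.shape[1])]
    elif len(label_names) != truth.shape[1]:
        raise ValueError("label_names length must match the number of columns")

    tp = ((predicted == 1) & (truth == 1)).sum(axis=0).astype(float)
    fp = ((predicted == 1) & (truth == 0)).sum(axis=0).astype(float)
    fn = ((predicted == 0) & (truth == 1)).sum(axis=0).astype(float)
    denom = 2 * tp + fp + fn
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    per_label = {str(n): float(v) for n, v in zip(label_names, f1)}
    return float(f1.mean()), per_label
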