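"""Imbalance-aware minibatch composition.

Each training iteration's minibatch holds a fixed number of original
samples plus a *supplementary batch* of synthetic entries drawn from the
minority or the medium classes.  Over an epoch, a deterministic schedule
allocates 65% of iterations to minority supplements and 35% to medium
supplements (seed-shuffled order):

* a **minority** supplement adds, per minority class, ``n`` triples of
  three images — one geometric/colour transform (GCT) of an original, one
  non-linear mixup about the red axis, one about the green axis;
* a **medium** supplement adds three GCT variants per contributing class,
  with classes rotating round-robin across iterations so all medium
  classes are used evenly; mixup operators never appear here, because the
  larger and more label-diverse medium classes would produce noisy
  intersected label sets.

The sampler emits :class:`BatchManifest` records — sample ids and synthetic
provenance, no pixels — so any training loop can materialize images lazily
through the augmentation module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from ._rng import derive_seed
from .augmentation import ThetaSampler
from .imbalance_metrics import ImbalanceProfile, LabelMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "SupplementRecord",
    "BatchManifest",
    "build_epoch_schedule",
    "build_minority_supplement",
    "build_medium_supplement",
    "compose_minibatch",
    "ImbalanceAwareSampler",
    "MINORITY_OPERATORS",
]

#: Operator triple added per minority class per unit of n.
MINORITY_OPERATORS = ("GCT", "NLmixupR", "NLmixupG")


@dataclass(frozen=True)
class SamplerConfig:
    """Minibatch composition parameters.

    Defaults follow the published configuration: 32-sample minibatches with
    17 originals, n = 1 synthetic triple per minority class, and 65% of
    iterations carrying the minority supplement.
    """

    batch_size: int = 32
    originals_per_batch: int = 17
    n: int = 1
    n_per_class: Mapping[str, int] | None = None
    minority_fraction: float = 0.65
    iterations_per_epoch: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.originals_per_batch < 1:
            raise ValueError("batch sizes must be positive")
        if self.originals_per_batch >= self.batch_size:
            raise ValueError("originals_per_batch must be < batch_size")
        if not 0.0 <= self.minority_fraction <= 1.0:
            raise ValueError("minority_fraction must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def supplement_capacity(self) -> int:
        return self.batch_size - self.originals_per_batch

    def n_for(self, class_id: str) -> int:
        if self.n_per_class and class_id in self.n_per_class:
            return int(self.n_per_class[class_id])
        return self.n


@dataclass(frozen=True)
class SupplementRecord:
    """Provenance of one synthetic entry in a supplementary batch."""

    class_id: str
    operator: str  # GCT | NLmixupR | NLmixupG
    parent_ids: tuple[str, ...]
    theta: float | None = None

    def to_dict(self) -> dict:
        d = {
            "class_id": self.class_id,
            "operator": self.operator,
            "parent_ids": list(self.parent_ids),
        }
        if self.theta is not None:
            d["theta"] = round(self.theta, 6)
        return d


@dataclass(frozen=True)
class BatchManifest:
    """One iteration's minibatch: originals plus synthetic supplement."""

    iteration_index: int
    kind: str  # minority | medium
    original_ids: tuple[str, ...]
    supplementary: tuple[SupplementRecord, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("minority", "medium"):
            raise ValueError(f"unknown iteration kind {self.kind!r}")

    @property
    def size(self) -> int:
        return len(self.original_ids) + len(self.supplementary)

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration_index,
            "kind": self.kind,
            "original_ids": list(self.original_ids),
            "supplementary": [r.to_dict() for r in self.supplementary],
        }


def build_epoch_schedule(config: SamplerConfig) -> list[str]:
    """Deterministic iteration-kind allocation for one epoch.

    Exactly ``round(minority_fraction * K)`` of the K iterations are
    ``minority`` (round half up), the rest ``medium``; the order is
    shuffled by the config seed.
    """
    K = config.iterations_per_epoch
    if K < 1:
        raise ValueError("iterations_per_epoch must be >= 1")
    n_minority = int(np.floor(config.minority_fraction * K + 0.5))
    kinds = ["minority"] * n_minority + ["medium"] * (K - n_minority)
    rng = np.random.default_rng(derive_seed(config.seed, "schedule"))
    rng.shuffle(kinds)
    return kinds


def _draw_pair(ids: Sequence[str], rng: np.random.Generator, class_id: str) -> tuple[str, str]:
    if len(ids) == 1:
        logger.warning(
            "class %s has a single sample; mixup pair is self-paired", class_id
        )
        return ids[0], ids[0]
    i, j = rng.choice(len(ids), size=2, replace=False)
    return ids[int(i)], ids[int(j)]


def build_minority_supplement(
    classes: Sequence[str],
    pool: Mapping[str, Sequence[str]],
    n: int | SamplerConfig,
    seed: int,
    capacity: int | None = None,
    theta_sampler: ThetaSampler | None = None,
) -> list[SupplementRecord]:
    """Synthetic entries for a minority iteration.

    Per minority class, ``n`` triples: a GCT of one random original, a
    non-linear mixup about R and one about G, each mixup built from a
    random same-class pair (self-paired with a warning when the class has a
    single sample).  If the total exceeds ``capacity`` the list is
    truncated class-round-robin; if it falls short, the remaining slots are
    filled with extra GCT variants of minority originals so the minibatch
    size stays fixed.
    """
    config = n if isinstance(n, SamplerConfig) else None
    rng = np.random.default_rng(seed)
    for c in classes:
        if not pool.get(c):
            raise ValueError(f"minority class {c!r} has an empty sample pool")

    triples: dict[str, list[list[SupplementRecord]]] = {}
    for c in classes:
        ids = list(pool[c])
        n_c = config.n_for(c) if config else int(n)
        triples[c] = []
        for _ in range(n_c):
            original = ids[int(rng.integers(len(ids)))]
            triple = [SupplementRecord(c, "GCT", (original,))]
            for op in ("NLmixupR", "NLmixupG"):
                pa, pb = _draw_pair(ids, rng, c)
                theta = theta_sampler.draw() if theta_sampler else None
                triple.append(SupplementRecord(c, op, (pa, pb), theta=theta))
            triples[c].append(triple)

    # interleave triples class-round-robin: c0 t0, c1 t0, ..., c0 t1, ...
    records: list[SupplementRecord] = []
    depth = 0
    while any(depth < len(ts) for ts in triples.values()):
        for c in classes:
            if depth < len(triples[c]):
                records.extend(triples[c][depth])
        depth += 1

    if capacity is not None:
        if len(records) > capacity:
            logger.warning(
                "minority supplement (%d entries) exceeds capacity %d; truncating",
                len(records),
                capacity,
            )
            records = records[:capacity]
        while len(records) < capacity:
            c = classes[int(rng.integers(len(classes)))]
            original = pool[c][int(rng.integers(len(pool[c])))]
            records.append(SupplementRecord(c, "GCT", (original,)))
    return records


def build_medium_supplement(
    classes: Sequence[str],
    pool: Mapping[str, Sequence[str]],
    capacity: int,
    seed: int,
    start_index: int = 0,
) -> tuple[list[SupplementRecord], int]:
    """Synthetic entries for a medium iteration: GCT variants only.

    ``capacity // 3`` classes contribute this iteration, taken round-robin
    from ``start_index`` in the given class order; each contributes three
    GCT variants of one randomly drawn original.  Returns the records and
    the rotation index for the next medium iteration.  Leftover slots (when
    capacity is not a multiple of 3) are filled with extra GCT entries from
    the next classes in the rotation.
    """
    if not classes:
        raise ValueError("no medium classes available")
    if capacity < 1:
        raise ValueError("capacity must be positive")
    for c in classes:
        if not pool.get(c):
            raise ValueError(f"medium class {c!r} has an empty sample pool")

    rng = np.random.default_rng(seed)
    records: list[SupplementRecord] = []
    idx = start_index
    while len(records) < capacity:
        c = classes[idx % len(classes)]
        idx += 1
        original = pool[c][int(rng.integers(len(pool[c])))]
        take = min(3, capacity - len(records))
        records.extend(SupplementRecord(c, "GCT", (original,)) for _ in range(take))
    return records, idx % len(classes)


def compose_minibatch(
    iteration_index: int,
    kind: str,
    original_ids: Sequence[str],
    supplementary: Sequence[SupplementRecord],
    config: SamplerConfig,
) -> BatchManifest:
    """Assemble and validate one manifest (originals + supplement)."""
    manifest = BatchManifest(
        iteration_index=iteration_index,
        kind=kind,
        original_ids=tuple(original_ids),
        supplementary=tuple(supplementary),
    )
    if manifest.size != config.batch_size:
        raise ValueError(
            f"manifest size {manifest.size} != batch size {config.batch_size}"
        )
    return manifest


class ImbalanceAwareSampler:
    """Iterable of :class:`BatchManifest` records for a labelled dataset.

    Originals are drawn label-agnostically without replacement within an
    epoch (the pool is reshuffled with an epoch-derived seed, and recycled
    with a fresh shuffle if the epoch needs more draws than the dataset
    holds).  Supplements follow the 65/35 minority/medium schedule.
    """

    def __init__(
        self,
        labels: LabelMatrix,
        profile: ImbalanceProfile,
        config: SamplerConfig,
    ):
        self.labels = labels
        self.profile = profile
        self.config = config
        self.minority_classes = sorted(profile.minority, key=_class_sort_key)
        self.medium_classes = sorted(profile.medium, key=_class_sort_key)
        if not self.minority_classes:
            raise ValueError("profile has no minority classes")
        if not self.medium_classes:
            raise ValueError("profile has no medium classes")
        self.pool = {
            name: [
                labels.instance_ids[i]
                for i in np.flatnonzero(labels.entries[:, j])
            ]
            for j, name in enumerate(labels.label_names)
        }
        cap = config.supplement_capacity
        need = 3 * sum(config.n_for(c) for c in self.minority_classes)
        if cap % 3:
            logger.warning(
                "supplement capacity %d is not divisible into triples", cap
            )
        if need > cap:
            logger.warning(
                "minority supplement demand %d exceeds capacity %d; "
                "entries will be truncated round-robin",
                need,
                cap,
            )

    def epoch(self, epoch_index: int = 0) -> Iterator[BatchManifest]:
        config = self.config
        schedule = build_epoch_schedule(config)
        rng = np.random.default_rng(
            derive_seed(config.seed, "originals", epoch_index)
        )
        order = list(rng.permutation(len(self.labels.instance_ids)))
        cursor = 0
        theta = ThetaSampler(derive_seed(config.seed, "theta", epoch_index))
        medium_rotation = 0

        for it, kind in enumerate(schedule):
            originals = []
            for _ in range(config.originals_per_batch):
                if cursor >= len(order):
                    order = list(rng.permutation(len(self.labels.instance_ids)))
                    cursor = 0
                originals.append(self.labels.instance_ids[order[cursor]])
                cursor += 1
            sup_seed = derive_seed(config.seed, f"supplement-{epoch_index}", it)
            if kind == "minority":
                records = build_minority_supplement(
                    self.minority_classes,
                    self.pool,
                    config,
                    sup_seed,
                    capacity=config.supplement_capacity,
                    theta_sampler=theta,
                )
            else:
                records, medium_rotation = build_medium_supplement(
                    self.medium_classes,
                    self.pool,
                    config.supplement_capacity,
                    sup_seed,
                    start_index=medium_rotation,
                )
            yield compose_minibatch(it, kind, originals, records, config)

    def __iter__(self) -> Iterator[BatchManifest]:
        return self.epoch(0)


def _class_sort_key(name: str):
    try:
        return (0, int(name))
    except ValueError:
        return (1, name)
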