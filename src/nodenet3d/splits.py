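"""Stratified node-level splitting, ENE oversampling and geometric augmentation.

The split is stratified by node category (negative / NM without ENE / NM with
ENE).  Per-class counts are fixed by largest-remainder apportionment with a
house size of ``ceil(n * fraction)``, so counts are identical across seeds and
only the membership is random.  With class sizes (380, 153, 120) this yields a
20% test partition of 131 nodes (76/31/24) and, re-applying 20% to the 522
remaining, a validation partition of 105 (61/25/19) and training partition of
417 (243/97/77).

Class imbalance for the rare ENE class is handled by oversampling (with
replacement) in the training and validation partitions in parallel, and by
class-dependent geometric augmentation of the training set: every sample keeps
its original plus two flips and two rotations; metastatic samples add one more
rotation; ENE samples add a further combined flip-rotation.  Totals per
original sample: negative 5, NM-without-ENE 6, ENE 7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import LABELS
from .preprocess import NodeSample

__all__ = [
    "SplitPlan",
    "AugmentPlan",
    "largest_remainder",
    "stratified_split",
    "oversample_ene",
    "augment",
    "augment_partition",
]


def largest_remainder(class_sizes: dict[str, int], fraction: float) -> dict[str, int]:
    """Apportion ``ceil(total * fraction)`` slots across classes.

    Hamilton / largest-remainder: each class gets the floor of its quota
    ``size * fraction``; remaining slots go to the largest fractional
    remainders (ties broken by class order in ``class_sizes``).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    total = sum(class_sizes.values())
    house = math.ceil(total * fraction) if fraction > 0 else 0
    quotas = {c: n * fraction for c, n in class_sizes.items()}
    counts = {c: math.floor(q) for c, q in quotas.items()}
    leftover = house - sum(counts.values())
    order = sorted(class_sizes, key=lambda c: quotas[c] - counts[c], reverse=True)
    for c in order[:leftover]:
        counts[c] += 1
    return counts


@dataclass(frozen=True)
class SplitPlan:
    """Assignment of every node id to one of train / validation / test."""

    assignment: dict[str, str]
    counts: dict[str, dict[str, int]]  # partition -> class -> n
    seed: int

    def ids(self, partition: str) -> list[str]:
        return [nid for nid, p in self.assignment.items() if p == partition]

    def to_rows(self, labels: dict[str, str]) -> list[tuple[str, str, str]]:
        return [(nid, labels[nid], part) for nid, part in self.assignment.items()]


def stratified_split(
    labels: dict[str, str],
    test_frac: float = 0.20,
    val_frac: float = 0.20,
    seed: int = 0,
) -> SplitPlan:
    """Split node ids into train/validation/test, stratified by class.

    ``test_frac`` applies to the full cohort; ``val_frac`` applies to the
    remainder after the test partition is removed (the protocol's 64/16/20
    overall split corresponds to test_frac=0.20, val_frac=0.20).  Counts are
    deterministic (largest-remainder, house = ceil); membership within each
    class is drawn uniformly under ``seed``.
    """
    for frac in (test_frac, val_frac):
        if not 0 <= frac < 1:
            raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for nid, lab in labels.items():
        by_class.setdefault(lab, []).append(nid)
    # Stable class order: known labels first in canonical order, then others.
    class_order = [c for c in LABELS if c in by_class] + sorted(
        c for c in by_class if c not in LABELS
    )
    sizes = {c: len(by_class[c]) for c in class_order}
    test_counts = largest_remainder(sizes, test_frac)
    remainder = {c: sizes[c] - test_counts[c] for c in class_order}
    val_counts = largest_remainder(remainder, val_frac)

    assignment: dict[str, str] = {}
    counts = {p: {c: 0 for c in class_order} for p in ("train", "validation", "test")}
    for c in class_order:
        ids = sorted(by_class[c])
        perm = rng.permutation(len(ids))
        n_test, n_val = test_counts[c], val_counts[c]
        for rank, idx in enumerate(perm):
            if rank < n_test:
                part = "test"
            elif rank < n_test + n_val:
                part = "validation"
            else:
                part = "train"
            assignment[ids[idx]] = part
            counts[part][c] += 1
    return SplitPlan(assignment=assignment, counts=counts, seed=seed)


def oversample_ene(
    samples: list[NodeSample], factor: int = 2, seed: int = 0
) -> list[NodeSample]:
    """Boost the ENE class by ``factor`` via sampling with replacement.

    Each ENE sample appears once; ``(factor - 1) * n_ene`` additional ENE
    samples are drawn with replacement.  Other classes are untouched.  Apply
    to training and validation partitions in parallel; never to test.
    """
    if factor < 1:
        raise ValueError("oversampling factor must be >= 1")
    if factor == 1:
        return list(samples)
    rng = np.random.default_rng(seed)
    ene = [s for s in samples if s.ene == 1]
    out = list(samples)
    if ene:
        extra = rng.integers(0, len(ene), size=(factor - 1) * len(ene))
        out.extend(ene[i] for i in extra)
    return out


@dataclass(frozen=True)
class AugmentPlan:
    """Class-dependent augmentation recipe.

    Base ops for every class: 2 flips + 2 rotations.  Metastatic samples add
    one rotation; ENE samples add one flip-rotation.  The original is always
    kept, so per-sample totals are negative 5, NM 6, ENE 7.
    """

    base_flips: int = 2
    base_rotations: int = 2
    extra_nm_rotations: int = 1
    extra_ene_fliprotations: int = 1
    keep_original: bool = True
    angle_range_deg: tuple[float, float] = (-30.0, 30.0)
    seed: int = 0

    def copies_for(self, target: tuple[int, int]) -> int:
        n = self.base_flips + self.base_rotations
        if target[0]:
            n += self.extra_nm_rotations
        if target[1]:
            n += self.extra_ene_fliprotations
        return n + (1 if self.keep_original else 0)


def _flip(arr: np.ndarray, axis: int) -> np.ndarray:
    return np.flip(arr, axis=axis).copy()


def _rotate_inplane(arr: np.ndarray, angle_deg: float) -> np.ndarray:
    # In-plane (about z) rotation; bicubic resampling, zero fill outside.
    return ndimage.rotate(
        arr, angle_deg, axes=(0, 1), reshape=False, order=3, mode="constant", cval=0.0
    ).astype(arr.dtype)


def augment(sample: NodeSample, plan: AugmentPlan, rng: np.random.Generator | None = None) -> list[NodeSample]:
    """Return the original plus class-dependent augmented copies.

    Flips mirror the x or y axis; rotations are in-plane about z by an angle
    drawn uniformly from ``plan.angle_range_deg``.  Every geometric op is
    applied identically to the box and small inputs; targets and covariates
    are never altered.
    """
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    out: list[NodeSample] = []
    if plan.keep_original:
        out.append(sample)

    def emit(box, small, tag):
        out.append(
            replace(
                sample,
                box_input=box,
                small_input=small,
                node_id=f"{sample.node_id}#{tag}",
            )
        )

    for i in range(plan.base_flips):
        axis = int(rng.integers(0, 2))
        emit(_flip(sample.box_input, axis), _flip(sample.small_input, axis), f"flip{i}")
    n_rot = plan.base_rotations + (plan.extra_nm_rotations if sample.nm else 0)
    for i in range(n_rot):
        ang = float(rng.uniform(*plan.angle_range_deg))
        emit(
            _rotate_inplane(sample.box_input, ang),
            _rotate_inplane(sample.small_input, ang),
            f"rot{i}",
        )
    if sample.ene:
        for i in range(plan.extra_ene_fliprotations):
            axis = int(rng.integers(0, 2))
            ang = float(rng.uniform(*plan.angle_range_deg))
            emit(
                _rotate_inplane(_flip(sample.box_input, axis), ang),
                _rotate_inplane(_flip(sample.small_input, axis), ang),
                f"fliprot{i}",
            )
    return out


def augment_partition(
    samples: list[NodeSample], plan: AugmentPlan
) -> list[NodeSample]:
    """Augment every sample in a (training) partition with one seeded stream.

    Oversampled duplicates are augmented independently — each copy draws its
    own random angles.
    """
    rng = np.random.default_rng(plan.seed)
    out: list[NodeSample] = []
    for s in samples:
        out.extend(augment(s, plan, rng))
    return out
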