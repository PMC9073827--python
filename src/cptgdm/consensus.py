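"""Similarity-based expert weighting and the collective interval reference point.

Each of H experts states an interval reference point per criterion.  The
panel is min-max normalized per criterion (over all experts' bounds), each
expert's distance to the column-mean interval is measured by a root-mean-square
distance of the two bounds, and experts closer to the mean opinion receive
larger weights.  The collective reference point per criterion is the
weight-averaged interval of the experts' raw reference points, so it lives on
the original measurement scale of the criterion; the normalized panel is used
only to make distances comparable across criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import CriterionType, Interval

__all__ = [
    "ExpertPanel",
    "NormalizedPanel",
    "DistanceTable",
    "ExpertWeights",
    "CollectiveReference",
    "normalize_panel",
    "mean_reference",
    "distance_table",
    "expert_weights",
    "collective_reference",
    "derive_expert_weights",
]


def _to_interval_grid(entries: Sequence[Sequence[Interval]]) -> tuple[tuple[Interval, ...], ...]:
    return tuple(tuple(Interval.coerce(cell) for cell in row) for row in entries)


@dataclass(frozen=True)
class ExpertPanel:
    """H x K matrix of interval reference points, one row per expert."""

    entries: tuple[tuple[Interval, ...], ...]
    experts: tuple[str, ...] = ()
    criteria: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        entries = _to_interval_grid(self.entries)
        if len(entries) == 0 or len(entries[0]) == 0:
            raise ValueError("expert panel must have at least one expert and one criterion")
        k = len(entries[0])
        if any(len(row) != k for row in entries):
            raise ValueError("expert panel rows must all have the same number of criteria")
        object.__setattr__(self, "entries", entries)
        if not self.experts:
            object.__setattr__(self, "experts", tuple(f"E{h + 1}" for h in range(len(entries))))
        if not self.criteria:
            object.__setattr__(self, "criteria", tuple(f"C{j + 1}" for j in range(k)))
        if len(self.experts) != len(entries) or len(self.criteria) != k:
            raise ValueError("experts/criteria labels must match the entry grid shape")

    @property
    def n_experts(self) -> int:
        return len(self.entries)

    @property
    def n_criteria(self) -> int:
        return len(self.entries[0])

    def bounds(self) -> np.ndarray:
        """(H, K, 2) array of lower/upper bounds."""
        return np.array([[cell.as_pair() for cell in row] for row in self.entries], dtype=float)


@dataclass(frozen=True)
class NormalizedPanel:
    """Panel after per-criterion min-max normalization; all bounds in [0, 1]."""

    entries: tuple[tuple[Interval, ...], ...]

    def __post_init__(self) -> None:
        entries = _to_interval_grid(self.entries)
        for row in entries:
            for cell in row:
                if cell.lo < -1e-12 or cell.hi > 1 + 1e-12:
                    raise ValueError(f"normalized bounds must lie in [0, 1], got {cell}")
        object.__setattr__(self, "entries", entries)

    def bounds(self) -> np.ndarray:
        return np.array([[cell.as_pair() for cell in row] for row in self.entries], dtype=float)


@dataclass(frozen=True)
class DistanceTable:
    """Per-expert, per-criterion distances to the mean opinion and similarity scores."""

    d_hk: np.ndarray  # (H, K), each in [0, 1]
    d_h: np.ndarray  # (H,), similarity = sum_k (1 - d_hk)


@dataclass(frozen=True)
class ExpertWeights:
    """Nonnegative expert weights summing to one."""

    w_h: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w_h, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("expert weights must be a nonempty vector")
        if np.any(w < -1e-12):
            raise ValueError("expert weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"expert weights must sum to 1, got {w.sum()}")
        object.__setattr__(self, "w_h", w)


@dataclass(frozen=True)
class CollectiveReference:
    """Collective interval reference point per criterion, on the original scale."""

    r_k: tuple[Interval, ...] = field(default_factory=tuple)


def normalize_panel(
    panel: ExpertPanel,
    criterion_types: Sequence[CriterionType | str] | None = None,
) -> NormalizedPanel:
    """Min-max normalize each criterion column over all experts' bounds.

    Benefit criteria map linearly onto [0, 1]; cost criteria are reflected
    (``(max - x) / range``) with the resulting bounds reordered so lo <= hi.
    A column with zero range (all experts identical) normalizes to [0, 0] for
    every expert, so it contributes no distance.
    """
    bounds = panel.bounds()
    h, k, _ = bounds.shape
    if criterion_types is None:
        types = [CriterionType.BENEFIT] * k
    else:
        types = [CriterionType(t) for t in criterion_types]
        if len(types) != k:
            raise ValueError("criterion_types length must match the panel's criterion count")
    rows: list[list[Interval]] = [[] for _ in range(h)]
    for j in range(k):
        col = bounds[:, j, :]
        lo, hi = col.min(), col.max()
        rng = hi - lo
        for i in range(h):
            if rng == 0:
                cell = Interval(0.0, 0.0)
            elif types[j] is CriterionType.BENEFIT:
                cell = Interval((col[i, 0] - lo) / rng, (col[i, 1] - lo) / rng)
            else:
                a = (hi - col[i, 1]) / rng
                b = (hi - col[i, 0]) / rng
                cell = Interval(min(a, b), max(a, b))
            rows[i].append(cell)
    return NormalizedPanel(entries=tuple(tuple(r) for r in rows))


def mean_reference(norm: NormalizedPanel) -> list[Interval]:
    """Per-criterion arithmetic mean interval of the normalized panel."""
    bounds = norm.bounds()
    means = bounds.mean(axis=0)  # (K, 2)
    return [Interval(lo, hi) for lo, hi in means]


def distance_table(norm: NormalizedPanel, mean: Sequence[Interval]) -> DistanceTable:
    """Root-mean-square bound distance of each expert's interval to the column mean.

    d_hk = sqrt(((lo_hk - mean_lo)^2 + (hi_hk - mean_hi)^2) / 2), in [0, 1] on
    normalized data; the similarity score is d_h = sum_k (1 - d_hk).
    """
    bounds = norm.bounds()
    mean_arr = np.array([Interval.coerce(m).as_pair() for m in mean], dtype=float)
    if mean_arr.shape[0] != bounds.shape[1]:
        raise ValueError("mean reference length must match the panel's criterion count")
    d_hk = np.sqrt(((bounds - mean_arr[None, :, :]) ** 2).sum(axis=2) / 2.0)
    d_h = (1.0 - d_hk).sum(axis=1)
    return DistanceTable(d_hk=d_hk, d_h=d_h)


def expert_weights(dist: DistanceTable) -> ExpertWeights:
    """Normalize similarity scores into expert weights, w_h = d_h / sum d_h."""
    total = dist.d_h.sum()
    if total <= 0:
        raise ValueError(
            "total expert similarity is zero; cannot derive weights "
            "(every expert maximally distant from the mean opinion)"
        )
    return ExpertWeights(w_h=dist.d_h / total)


def collective_reference(panel: ExpertPanel, weights: ExpertWeights) -> CollectiveReference:
    """Weight-averaged interval reference point per criterion, on the raw scale."""
    w = weights.w_h
    bounds = panel.bounds()
    if w.shape[0] != bounds.shape[0]:
        raise ValueError("weight vector length must match the number of experts")
    agg = np.einsum("h,hkb->kb", w, bounds)
    return CollectiveReference(r_k=tuple(Interval(lo, hi) for lo, hi in agg))


def derive_expert_weights(
    panel: ExpertPanel,
    criterion_types: Sequence[CriterionType | str] | None = None,
) -> ExpertWeights:
    """Convenience chain: normalize, mean, distances, weights."""
    norm = normalize_panel(panel, criterion_types)
    return expert_weights(distance_table(norm, mean_reference(norm)))
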