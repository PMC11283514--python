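"""Scanpath transition matrices between AOIs.

A transition is a pair of consecutive fixations whose AOI memberships
differ; within-AOI transitions are excluded by construction, so the
diagonal is always zero. Because a fixation can hit several overlapping
AOIs, each consecutive pair contributes one count for every ordered
cross-pair (a, b) with a != b by default; a priority mode collapses each
membership set to a single AOI first (smallest area wins). Fixations
outside all AOIs break the chain: A -> outside -> B yields no A -> B
count (switchable with ``outside_breaks_chain=False``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AOILayout

__all__ = ["TransitionMatrix", "transitions", "pool_matrices", "priority_by_area"]


@dataclass(frozen=True)
class TransitionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray  # square, int, zero diagonal

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts", counts)
        n = len(self.labels)
        if counts.shape != (n, n):
            raise ValidationError("counts must be square and match labels")
        if np.any(counts < 0):
            raise ValidationError("transition counts must be non-negative")
        if np.any(np.diagonal(counts) != 0):
            raise ValidationError("within-AOI transitions are excluded; diagonal must be 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, src: str, dst: str) -> int:
        return int(self.counts[self.labels.index(src), self.labels.index(dst)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def priority_by_area(layout: AOILayout) -> list[str]:
    """AOI names ordered smallest-area first, for priority-mode counting."""
    return [a.name for a in sorted(layout, key=lambda a: (a.area, a.name))]


def _resolve(assignment: frozenset[str], priority: Sequence[str]) -> frozenset[str]:
    for name in priority:
        if name in assignment:
            return frozenset({name})
    return frozenset()


def transitions(
    assignment_sequence: Sequence[frozenset[str]],
    labels: Sequence[str],
    outside_breaks_chain: bool = True,
    overlap_mode: str = "all_pairs",
    priority: Sequence[str] | None = None,
) -> TransitionMatrix:
    """Count between-AOI transitions over consecutive fixation pairs.

    ``assignment_sequence`` is the per-fixation AOI membership sets in
    onset order, as produced by :func:`gazekit.aoi.assign_fixations`.
    """
    if overlap_mode not in ("all_pairs", "priority"):
        raise ValidationError(f"unknown overlap_mode {overlap_mode!r}")
    labels = tuple(labels)
    index = {name: i for i, name in enumerate(labels)}
    seq = [frozenset(a) for a in assignment_sequence]
    for a in seq:
        unknown = a - index.keys()
        if unknown:
            raise ValidationError(f"assignment references unknown AOIs: {sorted(unknown)}")
    if overlap_mode == "priority":
        prio = list(priority) if priority is not None else list(labels)
        prio += [name for name in labels if name not in prio]
        seq = [_resolve(a, prio) for a in seq]
    if not outside_breaks_chain:
        seq = [a for a in seq if a]

    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for cur, nxt in zip(seq[:-1], seq[1:]):
        for a in cur:
            for b in nxt:
                if a != b:
                    counts[index[a], index[b]] += 1
    return TransitionMatrix(labels=labels, counts=counts)


def pool_matrices(matrices: Sequence[TransitionMatrix]) -> TransitionMatrix:
    """Element-wise sum of matrices sharing one label set (e.g. per condition)."""
    if not matrices:
        raise ValidationError("cannot pool an empty collection of matrices")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValidationError("cannot pool matrices with different label sets")
    total = np.sum([m.counts for m in matrices], axis=0)
    return TransitionMatrix(labels=labels, counts=total)
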