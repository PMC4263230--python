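"""Genomic interval primitives and interval algebra.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Intervals that merely share a boundary (``end == start``) do not overlap.
Strand is carried as metadata but ignored by all overlap computations.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort by (chrom, start, end); chromosome names compare lexicographically."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def _by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        out[iv.chrom].append(iv)
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals overlapping by >= 1 bp into maximal atomic regions.

    Book-ended intervals (sharing only a boundary under the half-open
    convention) are kept separate.  The result is sorted and pairwise
    disjoint, and covers exactly the same set of bases as the input.
    """
    merged: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        ivs = sorted(
            (iv for iv in intervals if iv.chrom == chrom),
            key=lambda iv: (iv.start, iv.end),
        )
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_e:  # >=1 shared base
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def overlap_pairs(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    min_bp: int = 1,
) -> list[tuple[int, int]]:
    """All index pairs (i, j) with >= min_bp shared bases between a[i] and b[j].

    Both inputs must be sorted by (chrom, start, end).  Each qualifying pair
    is reported exactly once, in order of the first index.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    _check_sorted(set_a, "set_a")
    _check_sorted(set_b, "set_b")
    b_index: dict[str, list[tuple[int, GenomicInterval]]] = defaultdict(list)
    for j, iv in enumerate(set_b):
        b_index[iv.chrom].append((j, iv))
    pairs: list[tuple[int, int]] = []
    for i, a in enumerate(set_a):
        cand = b_index.get(a.chrom)
        if not cand:
            continue
        starts = np.fromiter((iv.start for _, iv in cand), dtype=np.int64)
        # candidates must start before a.end - (min_bp - 1)
        hi = int(np.searchsorted(starts, a.end - min_bp, side="right"))
        for j, b in cand[:hi]:
            if min(a.end, b.end) - max(a.start, b.start) >= min_bp:
                pairs.append((i, j))
    return pairs


def _check_sorted(ivs: Sequence[GenomicInterval], name: str) -> None:
    keys = [(iv.chrom, iv.start, iv.end) for iv in ivs]
    if keys != sorted(keys):
        raise ValueError(f"{name} must be sorted by (chrom, start, end)")


@dataclass
class IntervalIndex:
    """Searchsorted-backed membership/overlap queries over a sorted interval set.

    Intervals are merged internally, so queries answer "does the query touch
    any base covered by the set" / "which merged region does it hit".
    """

    intervals: Sequence[GenomicInterval]
    _starts: dict[str, np.ndarray] = field(init=False, repr=False)
    _ends: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        merged = merge_intervals(list(self.intervals))
        self._starts, self._ends = {}, {}
        for chrom, ivs in _by_chrom(merged).items():
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    def overlaps_any(self, chrom: str, start, end) -> np.ndarray:
        """Vectorised: does [start, end) share >=1 bp with any set interval?"""
        start = np.atleast_1d(np.asarray(start, dtype=np.int64))
        end = np.atleast_1d(np.asarray(end, dtype=np.int64))
        if chrom not in self._starts:
            return np.zeros(start.shape, dtype=bool)
        s, e = self._starts[chrom], self._ends[chrom]
        # an overlap exists iff some interval has start < end_q and end > start_q
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        return hi > lo

    def contains_point(self, chrom: str, pos) -> np.ndarray:
        """Vectorised: is position (or float midpoint) inside any set interval?"""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.float64))
        if chrom not in self._starts:
            return np.zeros(pos.shape, dtype=bool)
        s, e = self._starts[chrom], self._ends[chrom]
        idx = np.searchsorted(s, pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < e[idx[ok]]
        return out

    def interval_overlap_flags(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        flags = np.zeros(len(intervals), dtype=bool)
        for chrom, idxs in _group_indices(intervals).items():
            sub = [intervals[i] for i in idxs]
            hit = self.overlaps_any(
                chrom,
                [iv.start for iv in sub],
                [iv.end for iv in sub],
            )
            flags[np.asarray(idxs)] = hit
        return flags


def _group_indices(intervals: Sequence[GenomicInterval]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = defaultdict(list)
    for i, iv in enumerate(intervals):
        out[iv.chrom].append(i)
    return out


def count_overlapping(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> int:
    """Number of query intervals sharing >=1 bp with any subject interval."""
    if not query or not subject:
        return 0
    return int(IntervalIndex(subject).interval_overlap_flags(query).sum())


def shuffle_starts(
    lengths: np.ndarray, chrom_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform starts on [0, chrom_length - length] for each peak length."""
    if np.any(lengths > chrom_length):
        raise ValueError("peak longer than chromosome")
    return rng.integers(0, chrom_length - lengths + 1)
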