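"""Windowed divergence features from a whole-genome alignment.

The reference chromosome is partitioned into fixed-size windows (100 kb by
default).  For each window three proportions are measured from the alignment
of the two parental chromosomes:

``V``
    variants — SNP and deletion positions per reference window, as a
    proportion of the window length (insertions in the query have no
    reference position of their own and are excluded);
``I``
    inversions — the fraction of reference bases covered by at least one
    reverse-orientation alignment block (a per-base union, so overlapping
    blocks are not double-counted);
``A``
    absent bases — query bases with no alignment to the reference, attributed
    to the reference window at the junction between their flanking blocks.

The windowed sequence identity is then ``Id0 = 1 - (V + I + A)``, clipped to
[0, 1]: identical windows score 1 and every class of divergence linearly
penalises the score.  CentO satellite hit counts per window, used downstream
for centromere localisation, are computed on the same grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignio import AlignmentBlock, VariantRecord


@dataclass(frozen=True)
class WindowGrid:
    """Partition of a chromosome into fixed-size windows.

    The last window may be partial; per-window proportions are always
    normalised by the actual window length, not the nominal size, so feature
    values are not inflated at the chromosome end.
    """

    chrom_length: int
    window_size: int = 100_000
    chrom: str = "chr01"

    def __post_init__(self):
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")

    @property
    def n(self) -> int:
        return math.ceil(self.chrom_length / self.window_size)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n, dtype=np.int64) * self.window_size

    @property
    def window_lengths(self) -> np.ndarray:
        """Actual length of each window (last one may be partial)."""
        lengths = np.full(self.n, self.window_size, dtype=np.int64)
        lengths[-1] = self.chrom_length - (self.n - 1) * self.window_size
        return lengths

    def index_of(self, pos: int) -> int:
        """Window index containing 0-based position ``pos``."""
        if pos < 0 or pos >= self.chrom_length:
            raise ValueError(f"position {pos} outside chromosome [0, {self.chrom_length})")
        return pos // self.window_size


@dataclass
class FeatureTrack:
    """Per-window V, I, A proportions and the identity track Id0."""

    V: np.ndarray
    I: np.ndarray
    A: np.ndarray
    Id0: np.ndarray
    grid: WindowGrid

    def __post_init__(self):
        for name in ("V", "I", "A", "Id0"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != self.grid.n:
                raise ValueError(f"{name} has length {len(arr)}, grid has {self.grid.n}")
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"{name} values must lie in [0, 1]")

    @classmethod
    def from_alignment(
        cls,
        blocks: list[AlignmentBlock],
        variants: list[VariantRecord],
        grid: WindowGrid,
        qry_length: int,
    ) -> "FeatureTrack":
        """Full feature extraction from parsed alignment reports."""
        V = compute_variants(variants, grid)
        I = compute_inversions(blocks, grid)
        A = compute_absent(blocks, grid, qry_length)
        return cls(V=V, I=I, A=A, Id0=compute_identity(V, I, A), grid=grid)


@dataclass
class CentoTrack:
    """Per-window count of bases aligned to the CentO centromeric satellite."""

    counts: np.ndarray
    grid: WindowGrid

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.grid.n:
            raise ValueError("counts length does not match grid")
        if (self.counts < 0).any():
            raise ValueError("CentO counts must be non-negative")


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def _overlap_counts(intervals, grid: WindowGrid) -> np.ndarray:
    """Sum of interval overlap (in bases) with each window."""
    counts = np.zeros(grid.n, dtype=np.int64)
    ws = grid.window_size
    for s, e in intervals:
        w0, w1 = s // ws, (e - 1) // ws
        for w in range(w0, w1 + 1):
            lo = max(s, w * ws)
            hi = min(e, (w + 1) * ws, grid.chrom_length)
            if hi > lo:
                counts[w] += hi - lo
    return counts


def compute_inversions(blocks: list[AlignmentBlock], grid: WindowGrid) -> np.ndarray:
    """Proportion of reference bases per window covered by reverse blocks."""
    for b in blocks:
        if b.ref_end > grid.chrom_length:
            raise ValueError(
                f"block [{b.ref_start}, {b.ref_end}) extends past chromosome "
                f"length {grid.chrom_length}"
            )
    rev = _merge_intervals(
        [(b.ref_start, b.ref_end) for b in blocks if b.reverse]
    )
    return _overlap_counts(rev, grid) / grid.window_lengths


def compute_absent(
    blocks: list[AlignmentBlock], grid: WindowGrid, qry_length: int
) -> np.ndarray:
    """Proportion of absent (unaligned) query bases attributed per window.

    Unaligned query segments are located between their flanking blocks in
    query order; each segment's length is attributed to the reference window
    containing the midpoint between the reference projections of those
    flanking blocks.  Unaligned query termini attach to the first/last
    aligned reference base.  The resulting proportion is clipped at 1.
    """
    if not blocks:
        raise ValueError("cannot attribute absent bases without alignment blocks")
    max_covered = max(b.qry_end for b in blocks)
    if qry_length < max_covered:
        raise ValueError(
            f"qry_length {qry_length} < max covered query coordinate {max_covered}"
        )
    for b in blocks:
        if b.ref_end > grid.chrom_length:
            raise ValueError(
                f"block [{b.ref_start}, {b.ref_end}) extends past chromosome "
                f"length {grid.chrom_length}"
            )

    by_qry = sorted(blocks, key=lambda b: (b.qry_start, b.qry_end))
    absent = np.zeros(grid.n, dtype=np.int64)

    first_ref = min(b.ref_start for b in blocks)
    last_ref = max(b.ref_end for b in blocks) - 1

    # leading / trailing unaligned query termini
    lead = by_qry[0].qry_start
    if lead > 0:
        absent[grid.index_of(first_ref)] += lead
    covered_end = max(b.qry_end for b in by_qry)
    trail = qry_length - covered_end
    if trail > 0:
        absent[grid.index_of(last_ref)] += trail

    # interior gaps between consecutive blocks in query order
    cursor_end = by_qry[0].qry_end
    cursor_block = by_qry[0]
    for b in by_qry[1:]:
        gap = b.qry_start - cursor_end
        if gap > 0:
            junction = (cursor_block.ref_end - 1 + b.ref_start) // 2
            junction = min(max(junction, 0), grid.chrom_length - 1)
            absent[grid.index_of(junction)] += gap
        if b.qry_end > cursor_end:
            cursor_end = b.qry_end
            cursor_block = b

    return np.minimum(absent / grid.window_lengths, 1.0)


def compute_variants(variants: list[VariantRecord], grid: WindowGrid) -> np.ndarray:
    """Proportion of SNP and deletion positions per window.

    Insertion-in-query records (reference gap ``'.'``) carry no reference base
    and are excluded from the count.
    """
    counts = np.zeros(grid.n, dtype=np.int64)
    for v in variants:
        if v.is_insertion:
            continue
        if v.pos >= grid.chrom_length:
            raise ValueError(
                f"variant position {v.pos} beyond chromosome length {grid.chrom_length}"
            )
        counts[v.pos // grid.window_size] += 1
    return counts / grid.window_lengths


def compute_identity(V: np.ndarray, I: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Windowed identity Id0 = 1 - (V + I + A), clipped to [0, 1]."""
    V, I, A = (np.asarray(x, dtype=float) for x in (V, I, A))
    if not (len(V) == len(I) == len(A)):
        raise ValueError("V, I, A must have equal lengths")
    return np.clip(1.0 - (V + I + A), 0.0, 1.0)


def count_cento_hits(hits, grid: WindowGrid) -> CentoTrack:
    """CentO satellite alignment base counts per window.

    ``hits`` may be AlignmentBlocks or (start, end) 0-based half-open
    intervals on the chromosome's coordinate frame.  Hits straddling a window
    boundary are split; every aligned base of every hit is counted, so
    overlapping hits accumulate.
    """
    intervals = []
    for h in hits:
        if isinstance(h, AlignmentBlock):
            s, e = h.ref_start, h.ref_end
        else:
            s, e = int(h[0]), int(h[1])
        if s < 0 or e > grid.chrom_length or s >= e:
            raise ValueError(f"hit [{s}, {e}) outside chromosome [0, {grid.chrom_length})")
        intervals.append((s, e))
    return CentoTrack(counts=_overlap_counts(intervals, grid), grid=grid)
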