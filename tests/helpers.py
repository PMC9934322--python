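"""Independent brute-force oracles used to cross-check the fast implementations.

Everything here works base-by-base on explicit arrays, deliberately ignoring
the interval arithmetic of the library code it checks.
"""

from __future__ import annotations

import numpy as np

from recland.alignio import AlignmentBlock, VariantRecord
from recland.features import WindowGrid


def per_base_inversions(blocks, grid: WindowGrid) -> np.ndarray:
    """I(w) by marking every reverse-covered reference base."""
    covered = np.zeros(grid.chrom_length, dtype=bool)
    for b in blocks:
        if b.reverse:
            covered[b.ref_start : b.ref_end] = True
    return _window_means(covered.astype(np.int64), grid)


def per_base_variants(variants, grid: WindowGrid) -> np.ndarray:
    """V(w) by incrementing a per-base counter for non-insertion records."""
    counts = np.zeros(grid.chrom_length, dtype=np.int64)
    for v in variants:
        if v.ref_base != ".":
            counts[v.pos] += 1
    return _window_means(counts, grid)


def per_base_absent(blocks, grid: WindowGrid, qry_length: int) -> np.ndarray:
    """A(w) from a per-base query coverage array.

    Maximal uncovered query runs are attributed to the reference window at
    the midpoint between the reference projections of the blocks flanking
    the run in query order (termini to the first/last aligned reference
    base), then clipped at 1 — the same attribution rule, derived from the
    coverage array rather than from block adjacency.
    """
    coverage = np.zeros(qry_length, dtype=bool)
    for b in blocks:
        coverage[b.qry_start : b.qry_end] = True
    attributed = np.zeros(grid.n, dtype=np.int64)
    first_ref = min(b.ref_start for b in blocks)
    last_ref = max(b.ref_end for b in blocks) - 1

    runs = []
    in_run = False
    for q in range(qry_length + 1):
        uncov = q < qry_length and not coverage[q]
        if uncov and not in_run:
            start, in_run = q, True
        elif not uncov and in_run:
            runs.append((start, q))
            in_run = False
    for s, e in runs:
        left = [b for b in blocks if b.qry_end <= s]
        right = [b for b in blocks if b.qry_start >= e]
        if not left:
            point = first_ref
        elif not right:
            point = last_ref
        else:
            lb = max(left, key=lambda b: b.qry_end)
            rb = min(right, key=lambda b: b.qry_start)
            point = (lb.ref_end - 1 + rb.ref_start) // 2
        point = min(max(point, 0), grid.chrom_length - 1)
        attributed[point // grid.window_size] += e - s
    return np.minimum(attributed / grid.window_lengths, 1.0)


def per_base_cento_counts(hits, grid: WindowGrid) -> np.ndarray:
    """CentO counts by incrementing every aligned base of every hit."""
    counts = np.zeros(grid.chrom_length, dtype=np.int64)
    for h in hits:
        s, e = (h.ref_start, h.ref_end) if isinstance(h, AlignmentBlock) else h
        counts[s:e] += 1
    out = np.zeros(grid.n, dtype=np.int64)
    for w in range(grid.n):
        out[w] = counts[w * grid.window_size : (w + 1) * grid.window_size].sum()
    return out


def _window_means(per_base: np.ndarray, grid: WindowGrid) -> np.ndarray:
    out = np.zeros(grid.n)
    for w in range(grid.n):
        seg = per_base[w * grid.window_size : (w + 1) * grid.window_size]
        out[w] = seg.sum() / len(seg)
    return out


def literal_case_rules(id0: float, V: float, A: float, p) -> tuple[str, float]:
    """Direct transcription of the three case guards, first match wins."""
    if id0 < p.t1 and V > p.t4:
        return "case1", id0 - p.p1
    if id0 < p.t2 and V < p.t4:
        return "case2", id0 + p.p2
    if A > p.t3 and V < p.t4:
        return "case3", id0 - p.p3
    return "none", id0


def smoothing_closed_form(id3: np.ndarray, alpha: float) -> np.ndarray:
    """Id4(w) = alpha * sum_{j=1..w} (1-alpha)^(w-j) Id3(j); Id4(0) = 0."""
    n = len(id3)
    out = np.zeros(n)
    for w in range(1, n):
        js = np.arange(1, w + 1)
        out[w] = alpha * np.sum((1 - alpha) ** (w - js) * id3[js])
    return out
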