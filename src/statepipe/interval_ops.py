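"""Interval algebra for peak sets.

All coordinates are 0-based half-open (BED convention): an interval covers
bases ``start .. end-1`` and its length is ``end - start``.  Peak sets are
plain :class:`pandas.DataFrame` objects with at least the columns
``chrom``, ``start``, ``end``; ``name`` and ``score`` are carried through
when present.

The operations here are the kernel behind peak merging, reciprocal-overlap
intersection (the ``-f 0.25 -F 0.25 -e`` style criterion), shared/union peak
accounting, nearest-TSS target assignment and Fisher overlap enrichment.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

BED_COLUMNS = ["chrom", "start", "end"]


class SharedPeakCounts(NamedTuple):
    """Shared/exclusive accounting for two merged peak sets.

    ``n_shared`` is the number of disjoint regions in the merged union of
    qualifying intervals from both sets — a single number that can be quoted
    against either set's total, matching how shared-peak fractions are
    normally reported.  Per-set qualifying counts are kept alongside because
    the two readings coincide only when qualifying intervals pair one-to-one.
    """

    n_shared: int
    n_a_only: int
    n_b_only: int
    n_a_qualifying: int
    n_b_qualifying: int


def _validate(intervals: pd.DataFrame) -> pd.DataFrame:
    for col in BED_COLUMNS:
        if col not in intervals.columns:
            raise ValueError(f"interval table lacks required column {col!r}")
    starts = np.asarray(intervals["start"])
    ends = np.asarray(intervals["end"])
    if len(intervals) and (starts < 0).any():
        raise ValueError("negative start coordinate")
    if len(intervals) and (starts >= ends).any():
        raise ValueError("intervals must satisfy start < end (0-based half-open)")
    return intervals


def merge_overlapping(peaksets: Iterable[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping and book-ended intervals across one or more peak sets.

    Returns a peak set whose intervals are pairwise disjoint per chromosome,
    covering exactly the union of input bases.  Book-ended intervals
    (gap 0, e.g. [100,200) and [200,300)) merge, matching default
    ``bedtools merge`` semantics.  Idempotent.
    """
    if isinstance(peaksets, pd.DataFrame):
        frames = [peaksets]
    else:
        frames = list(peaksets)
    frames = [_validate(f) for f in frames]
    allint = pd.concat(
        [f[BED_COLUMNS] for f in frames], ignore_index=True
    ) if frames else pd.DataFrame(columns=BED_COLUMNS)
    if allint.empty:
        return pd.DataFrame({"chrom": [], "start": [], "end": [], "name": []})
    allint = allint.sort_values(["chrom", "start", "end"], kind="mergesort")
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    cur_chrom = None
    cur_start = cur_end = 0
    for chrom, start, end in allint.itertuples(index=False):
        if chrom != cur_chrom or start > cur_end:
            if cur_chrom is not None:
                out_chrom.append(cur_chrom)
                out_start.append(cur_start)
                out_end.append(cur_end)
            cur_chrom, cur_start, cur_end = chrom, start, end
        else:
            cur_end = max(cur_end, end)
    out_chrom.append(cur_chrom)
    out_start.append(cur_start)
    out_end.append(cur_end)
    merged = pd.DataFrame(
        {
            "chrom": out_chrom,
            "start": np.asarray(out_start, dtype=np.int64),
            "end": np.asarray(out_end, dtype=np.int64),
        }
    )
    merged["name"] = [f"merged_{i}" for i in range(1, len(merged) + 1)]
    return merged


def _overlap_candidates(a_start: int, a_end: int, b_starts: np.ndarray,
                        b_ends: np.ndarray) -> slice:
    """Index range of sorted disjoint B intervals overlapping [a_start, a_end)."""
    lo = int(np.searchsorted(b_ends, a_start, side="right"))
    hi = int(np.searchsorted(b_starts, a_end, side="left"))
    return slice(lo, hi)


def reciprocal_overlap_mask(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    min_frac: float = 0.25,
    either: bool = True,
) -> np.ndarray:
    """Boolean mask over ``set_a``: which intervals have a qualifying partner in B.

    An A interval ``a`` qualifies with a B interval ``b`` sharing ``L`` bases iff

    * ``either=True`` (the ``-f f -F f -e`` reading): ``L >= min_frac*len(a)``
      OR ``L >= min_frac*len(b)``;
    * ``either=False``: both conditions must hold (mutual coverage).

    Both sets must be merged (disjoint within set). The qualification decision
    is symmetric for the pair (a, b) in either mode.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must lie in (0, 1]")
    _validate(set_a)
    _validate(set_b)
    mask = np.zeros(len(set_a), dtype=bool)
    if set_a.empty or set_b.empty:
        return mask
    b_sorted = set_b.sort_values(["chrom", "start"], kind="mergesort")
    b_by_chrom = {
        chrom: (
            np.asarray(grp["start"], dtype=np.int64),
            np.asarray(grp["end"], dtype=np.int64),
        )
        for chrom, grp in b_sorted.groupby("chrom", sort=False)
    }
    chroms = np.asarray(set_a["chrom"])
    starts = np.asarray(set_a["start"], dtype=np.int64)
    ends = np.asarray(set_a["end"], dtype=np.int64)
    for i in range(len(set_a)):
        cb = b_by_chrom.get(chroms[i])
        if cb is None:
            continue
        b_starts, b_ends = cb
        sl = _overlap_candidates(starts[i], ends[i], b_starts, b_ends)
        if sl.start >= sl.stop:
            continue
        ov = np.minimum(ends[i], b_ends[sl.start:sl.stop]) - np.maximum(
            starts[i], b_starts[sl.start:sl.stop]
        )
        len_a = ends[i] - starts[i]
        len_b = b_ends[sl.start:sl.stop] - b_starts[sl.start:sl.stop]
        frac_a = ov / len_a
        frac_b = ov / len_b
        if either:
            hit = (frac_a >= min_frac) | (frac_b >= min_frac)
        else:
            hit = (frac_a >= min_frac) & (frac_b >= min_frac)
        mask[i] = bool(hit.any())  # candidates always overlap by >=1 base
    return mask


def reciprocal_overlap(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    min_frac: float = 0.25,
    either: bool = True,
) -> pd.DataFrame:
    """Subset of ``set_a`` intervals with a qualifying partner in ``set_b``."""
    mask = reciprocal_overlap_mask(set_a, set_b, min_frac=min_frac, either=either)
    return set_a.loc[mask].reset_index(drop=True)


def shared_peak_count(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    min_frac: float = 0.25,
    either: bool = True,
) -> SharedPeakCounts:
    """Shared/exclusive peak counting between two merged sets.

    The shared count is the number of merged regions in the union of
    qualifying A and B intervals; exclusive counts are per-set totals minus
    per-set qualifying counts.
    """
    mask_a = reciprocal_overlap_mask(set_a, set_b, min_frac=min_frac, either=either)
    mask_b = reciprocal_overlap_mask(set_b, set_a, min_frac=min_frac, either=either)
    qual_a = set_a.loc[mask_a]
    qual_b = set_b.loc[mask_b]
    if qual_a.empty and qual_b.empty:
        n_shared = 0
    else:
        n_shared = len(merge_overlapping([qual_a, qual_b] if not qual_a.empty and not qual_b.empty
                                         else [qual_a if not qual_a.empty else qual_b]))
    return SharedPeakCounts(
        n_shared=n_shared,
        n_a_only=len(set_a) - int(mask_a.sum()),
        n_b_only=len(set_b) - int(mask_b.sum()),
        n_a_qualifying=int(mask_a.sum()),
        n_b_qualifying=int(mask_b.sum()),
    )


def overlap_fraction(numerator: int, denominator: int) -> float:
    """Percentage ``100 * numerator / denominator``, half-up rounded to 1 decimal."""
    if denominator == 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def union_count(n_a: int, n_b: int, n_shared: int) -> int:
    """Inclusion-exclusion peak-union count ``n_a + n_b - n_shared``."""
    if min(n_a, n_b, n_shared) < 0:
        raise ValueError("counts must be non-negative")
    total = n_a + n_b - n_shared
    if total < 0:
        raise ValueError("shared count exceeds combined totals")
    return total


def midpoint(start: int, end: int) -> int:
    """Interval midpoint, floor((start+end)/2)."""
    return (start + end) // 2


def assign_target_gene(
    peak: tuple[str, int, int] | pd.Series,
    tss_table: pd.DataFrame,
    max_dist: int = 20_000,
) -> str | None:
    """Nearest-TSS target-gene assignment.

    Distance is |peak midpoint - tss_position|; the nearest gene on the same
    chromosome is returned when the distance is strictly below ``max_dist``,
    else None.  Distance ties break to the lexicographically smaller gene id.
    ``tss_table`` needs columns gene_id, chrom, tss_position.
    """
    if tss_table.empty:
        raise ValueError("TSS table is empty")
    if isinstance(peak, pd.Series):
        chrom, start, end = peak["chrom"], int(peak["start"]), int(peak["end"])
    else:
        chrom, start, end = peak[0], int(peak[1]), int(peak[2])
    mid = midpoint(start, end)
    sub = tss_table[tss_table["chrom"] == chrom]
    if sub.empty:
        return None
    dist = (sub["tss_position"].to_numpy(dtype=np.int64) - mid)
    dist = np.abs(dist)
    best = dist.min()
    if best >= max_dist:
        return None
    genes = sub.loc[np.asarray(dist == best), "gene_id"]
    return sorted(genes)[0]


def annotate_peaks(
    peaks: pd.DataFrame, tss_table: pd.DataFrame, max_dist: int = 20_000
) -> pd.DataFrame:
    """Per-peak nearest-TSS gene assignment; gene is None beyond ``max_dist``."""
    genes = [
        assign_target_gene((row.chrom, row.start, row.end), tss_table, max_dist)
        for row in peaks.itertuples(index=False)
    ]
    out = peaks.copy()
    out["target_gene"] = genes
    return out


def fisher_overlap_test(n11: int, n12: int, n21: int, n22: int) -> float:
    """One-sided (greater) Fisher exact p for a 2x2 overlap table."""
    cells = (n11, n12, n21, n22)
    if any(c < 0 for c in cells):
        raise ValueError("contingency cells must be non-negative")
    _, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="greater")
    return float(p)
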