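"""Sorted-interval utilities (0-based half-open) used across the pipeline."""

from __future__ import annotations

import numpy as np

IntervalSet = dict[str, np.ndarray]  # chrom -> (n, 2) sorted, merged


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent-touching 0-based half-open intervals."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def make_interval_set(records) -> IntervalSet:
    """Build a merged IntervalSet from an iterable of (chrom, start, end)."""
    by_chrom: dict[str, list] = {}
    for chrom, start, end in records:
        by_chrom.setdefault(chrom, []).append((start, end))
    return {c: merge_intervals(np.array(v)) for c, v in by_chrom.items()}


def overlaps_any(starts: np.ndarray, ends: np.ndarray, merged: np.ndarray) -> np.ndarray:
    """Boolean mask: does [start, end) overlap any interval by >= 1 nt?

    ``merged`` must be sorted and merged (output of :func:`merge_intervals`).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if len(merged) == 0:
        return np.zeros(len(starts), dtype=bool)
    # candidate interval: last one starting before `end`
    idx = np.searchsorted(merged[:, 0], ends, side="left") - 1
    ok = idx >= 0
    hit = np.zeros(len(starts), dtype=bool)
    hit[ok] = merged[idx[ok], 1] > starts[ok]
    return hit


def overlap_fraction(starts, ends, interval_set: IntervalSet, chroms) -> float:
    """Fraction of intervals overlapping the set by >= 1 nt."""
    chroms = np.asarray(chroms)
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    if len(starts) == 0:
        raise ValueError("no intervals given")
    hit = np.zeros(len(starts), dtype=bool)
    for c in np.unique(chroms):
        m = chroms == c
        if c in interval_set:
            hit[m] = overlaps_any(starts[m], ends[m], interval_set[c])
    return float(hit.mean())
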