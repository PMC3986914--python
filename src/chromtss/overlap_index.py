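"""Fast any-overlap and bp-overlap queries against a fixed interval set.

Intervals are merged per chromosome into sorted disjoint blocks once;
queries then run in O(log n) via searchsorted. Merging happens only inside
this query structure — the caller's peak list itself is never mutated.
"""

from __future__ import annotations

import numpy as np

from .types import GenomicInterval


class IntervalIndex:
    def __init__(self, intervals: list[GenomicInterval]):
        self._blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in per_chrom.items():
            pairs.sort()
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.array(merged, dtype=np.int64)
            self._blocks[chrom] = (arr[:, 0], arr[:, 1])

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._blocks or end <= start:
            return False
        starts, ends = self._blocks[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(starts) and starts[i] < end

    def any_overlap_many(
        self, chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized any_overlap for parallel arrays of query intervals."""
        out = np.zeros(len(starts), dtype=bool)
        chroms = np.asarray(chroms, dtype=object)
        for chrom in np.unique(chroms):
            if chrom not in self._blocks:
                continue
            mask = chroms == chrom
            bs, be = self._blocks[chrom]
            idx = np.searchsorted(be, starts[mask], side="right")
            ok = idx < len(bs)
            hit = np.zeros(mask.sum(), dtype=bool)
            hit[ok] = bs[idx[ok]] < ends[mask][ok]
            out[mask] = hit
        return out

    def bp_overlap(self, chrom: str, start: int, end: int) -> int:
        """Total covered base pairs of [start, end)."""
        if chrom not in self._blocks or end <= start:
            return 0
        bs, be = self._blocks[chrom]
        lo = int(np.searchsorted(be, start, side="right"))
        hi = int(np.searchsorted(bs, end, side="left"))
        if lo >= hi:
            return 0
        s = np.maximum(bs[lo:hi], start)
        e = np.minimum(be[lo:hi], end)
        return int(np.sum(e - s))

    def total_bp(self) -> int:
        return int(
            sum((ends - starts).sum() for starts, ends in self._blocks.values())
        )
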