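"""Peak overlap counting and Monte-Carlo permutation p-values.

An RTSS counts as overlapping a mark if any enrichment peak intersects the
RTSS interval extended by 500 bp on each end (marks often sit just up- or
downstream of the TSS rather than on it). Significance comes from a Monte
Carlo null that uniformly repositions each RTSS within its chromosome,
preserving interval lengths and per-chromosome counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .overlap_index import IntervalIndex
from .types import GenomicInterval, RtssRecord

EXTENSION_BP = 500
N_PERMUTATIONS = 100


@dataclass
class OverlapStats:
    mark: str
    rtss_class: str
    n_rtss: int
    n_overlapping: int
    fraction: float
    p_value: float


def _extended_bounds(
    rtss_set: list[RtssRecord], extension: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    chroms = np.array([r.chrom for r in rtss_set], dtype=object)
    starts = np.array([max(0, r.interval.start - extension) for r in rtss_set])
    ends = np.array([r.interval.end + extension for r in rtss_set])
    return chroms, starts, ends


def count_overlaps(
    rtss_set: list[RtssRecord],
    peaks: list[GenomicInterval] | IntervalIndex,
    extension: int = EXTENSION_BP,
) -> tuple[int, float]:
    """Number and fraction of RTSSs whose extended interval hits any peak."""
    if extension < 0:
        raise ValueError("extension must be >= 0")
    index = peaks if isinstance(peaks, IntervalIndex) else IntervalIndex(peaks)
    if not rtss_set:
        return 0, 0.0
    chroms, starts, ends = _extended_bounds(rtss_set, extension)
    hits = index.any_overlap_many(chroms, starts, ends)
    n = int(hits.sum())
    return n, n / len(rtss_set)


def overlap_pvalue(
    rtss_set: list[RtssRecord],
    peaks: list[GenomicInterval] | IntervalIndex,
    chrom_sizes: dict[str, int],
    n_perm: int = N_PERMUTATIONS,
    seed: int | None = None,
    extension: int = EXTENSION_BP,
    tail: str = "enrichment",
) -> float:
    """Add-one Monte-Carlo p-value for peak overlap enrichment.

    Null: each RTSS interval is uniformly repositioned within its own
    chromosome (length preserved). Statistic: number of overlapping RTSSs.
    p = (1 + #{permuted >= observed}) / (1 + n_perm) for enrichment;
    the depletion tail counts permuted <= observed instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in ("enrichment", "depletion"):
        raise ValueError("tail must be 'enrichment' or 'depletion'")
    index = peaks if isinstance(peaks, IntervalIndex) else IntervalIndex(peaks)
    rng = np.random.default_rng(seed)
    observed, _ = count_overlaps(rtss_set, index, extension)

    chroms = np.array([r.chrom for r in rtss_set], dtype=object)
    lengths = np.array([len(r.interval) for r in rtss_set])
    maxstart = np.empty(len(rtss_set), dtype=np.int64)
    for i, r in enumerate(rtss_set):
        size = chrom_sizes[r.chrom]
        if len(r.interval) > size:
            raise ValueError(f"RTSS {r.id} longer than chromosome {r.chrom}")
        maxstart[i] = size - len(r.interval)

    exceed = 0
    for _ in range(n_perm):
        starts = rng.integers(0, maxstart + 1)
        ext_starts = np.maximum(0, starts - extension)
        ext_ends = starts + lengths + extension
        stat = int(index.any_overlap_many(chroms, ext_starts, ext_ends).sum())
        if tail == "enrichment":
            exceed += stat >= observed
        else:
            exceed += stat <= observed
    return (1 + exceed) / (1 + n_perm)


def overlap_stats(
    mark: str,
    rtss_class: str,
    rtss_set: list[RtssRecord],
    peaks: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    n_perm: int = N_PERMUTATIONS,
    seed: int | None = None,
    extension: int = EXTENSION_BP,
    tail: str = "enrichment",
) -> OverlapStats:
    index = IntervalIndex(peaks)
    n, frac = count_overlaps(rtss_set, index, extension)
    p = overlap_pvalue(
        rtss_set, index, chrom_sizes, n_perm, seed, extension, tail
    )
    return OverlapStats(mark, rtss_class, len(rtss_set), n, frac, p)
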