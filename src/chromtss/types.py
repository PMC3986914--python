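"""Core domain types.

All coordinates are 0-based half-open (BED convention) throughout the
package; readers for 1-based formats convert on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RtssRecord:
    """One robust TSS cluster (RTSS): an oriented interval with an anchor.

    The anchor is the region midpoint, ``floor((start+end)/2)``, and is the
    reference coordinate around which binned chromatin profiles are built.
    """

    id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"RTSS {self.id} must be stranded (+/-)")

    @property
    def anchor(self) -> int:
        return (self.interval.start + self.interval.end) // 2

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class ExpressionMatrix:
    """CAGE tag counts per RTSS per sample, wrapped around a DataFrame.

    Rows are RTSS ids, columns are sample ids, entries are non-negative
    integer tag counts.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative tag counts")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate RTSS ids in expression matrix")

    @property
    def rtss_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample(self, sample_id: str) -> pd.Series:
        if sample_id not in self.counts.columns:
            raise KeyError(f"sample {sample_id!r} not in expression matrix")
        return self.counts[sample_id]


@dataclass
class ReadStartSet:
    """Mapped-read 5' start positions for one chromatin mark.

    Stored column-wise as numpy arrays for fast windowed binning.
    """

    mark: str
    chroms: np.ndarray  # dtype object/str
    positions: np.ndarray  # int64, >= 0
    strands: np.ndarray  # '+'/'-'

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.chroms) == len(self.strands) == n):
            raise ValueError("ragged ReadStartSet columns")
        if n and self.positions.min() < 0:
            raise ValueError("negative read positions")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_records(
        cls, mark: str, entries: list[tuple[str, int, str]]
    ) -> "ReadStartSet":
        if not entries:
            return cls(
                mark,
                np.array([], dtype=object),
                np.array([], dtype=np.int64),
                np.array([], dtype=object),
            )
        chroms, pos, strands = zip(*entries)
        return cls(
            mark,
            np.asarray(chroms, dtype=object),
            np.asarray(pos, dtype=np.int64),
            np.asarray(strands, dtype=object),
        )


@dataclass
class SignalTrack:
    """Base-resolution signal held as sorted non-overlapping intervals.

    Per chromosome: parallel arrays (starts, ends, values). Query semantics
    are identical to a dense per-bp expansion with zero fill outside covered
    intervals.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def add_chrom(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray, values: np.ndarray
    ) -> None:
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping signal intervals on {chrom}")
        if not np.isfinite(values).all():
            raise ValueError(f"non-finite signal values on {chrom}")
        self.data[chrom] = (
            starts.astype(np.int64),
            ends.astype(np.int64),
            values.astype(float),
        )

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-bp values over [start, end); 0 outside coverage."""
        if chrom not in self.data or end <= start:
            return 0.0
        starts, ends, values = self.data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]))

    def window_sums(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Vector of window sums for consecutive windows given by edges."""
        return np.array(
            [
                self.window_sum(chrom, int(edges[i]), int(edges[i + 1]))
                for i in range(len(edges) - 1)
            ]
        )
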