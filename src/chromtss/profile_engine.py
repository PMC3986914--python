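"""Oriented, binned chromatin profiles around RTSS anchors.

A raw profile covers +/- 3 kbp around the anchor in 100 bp bins (60 bins).
Mapped-read start positions are first shifted +100 bp (+ strand) / -100 bp
(- strand) toward the fragment midpoint, then counted per bin. Profiles of
minus-strand RTSSs are reversed so the bin index always increases in the
transcript direction. Smoothing convolves with a normalized 7-bin Gaussian
and trims 6 bins from each end, reducing 60 bins to 48.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ReadStartSet, RtssRecord, SignalTrack

N_BINS_RAW = 60
N_BINS_SMOOTH = 48
BIN_BP = 100
FLANK_BP = 3000
SHIFT_BP = 100
MIN_READS = 100
KERNEL_WINDOW = 7
KERNEL_SIGMA = 1.5
TRIM_BINS = 6


@dataclass
class AverageProfile:
    mark: str
    rtss_class: str
    values: np.ndarray
    n_members: int


def shift_read_starts(reads: ReadStartSet, shift: int = SHIFT_BP) -> ReadStartSet:
    """Shift + strand reads by +shift, - strand by -shift; clip at 0."""
    if shift < 0:
        raise ValueError("shift must be >= 0")
    delta = np.where(reads.strands == "+", shift, -shift)
    return ReadStartSet(
        reads.mark,
        reads.chroms,
        np.maximum(reads.positions + delta, 0),
        reads.strands,
    )


def bin_profile(
    positions: np.ndarray,
    anchor: int,
    rtss_strand: str,
    bin_bp: int = BIN_BP,
    flank: int = FLANK_BP,
) -> np.ndarray:
    """Bin already-shifted read starts around one anchor.

    Window [anchor-flank, anchor+flank); position p lands in bin
    floor((p - anchor + flank) / bin_bp). Minus-strand output is reversed
    so index 0..n-1 runs upstream -> downstream in transcript orientation.
    """
    if flank % bin_bp:
        raise ValueError("flank must be divisible by bin_bp")
    n_bins = 2 * flank // bin_bp
    positions = np.asarray(positions)
    rel = positions - anchor + flank
    inside = (rel >= 0) & (rel < 2 * flank)
    counts = np.bincount(rel[inside] // bin_bp, minlength=n_bins).astype(float)
    if rtss_strand == "-":
        counts = counts[::-1]
    return counts


def profile_matrix(
    reads: ReadStartSet,
    catalog: list[RtssRecord],
    bin_bp: int = BIN_BP,
    flank: int = FLANK_BP,
    shift: int = SHIFT_BP,
) -> pd.DataFrame:
    """Raw profiles for a whole catalog against one mark's read set.

    Applies the strand shift, then bins per RTSS. Returns a DataFrame of
    shape (n_rtss, n_bins) indexed by RTSS id.
    """
    shifted = shift_read_starts(reads, shift)
    n_bins = 2 * flank // bin_bp
    out = np.zeros((len(catalog), n_bins))
    # group read positions per chromosome, sorted, and slice per RTSS window
    by_chrom: dict[str, np.ndarray] = {}
    chroms = np.asarray(shifted.chroms, dtype=object)
    for chrom in np.unique(chroms) if len(chroms) else []:
        by_chrom[chrom] = np.sort(shifted.positions[chroms == chrom])
    for i, r in enumerate(catalog):
        pos = by_chrom.get(r.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, r.anchor - flank, side="left")
        hi = np.searchsorted(pos, r.anchor + flank, side="left")
        out[i] = bin_profile(pos[lo:hi], r.anchor, r.strand, bin_bp, flank)
    return pd.DataFrame(out, index=[r.id for r in catalog])


def filter_low_signal(profiles: pd.DataFrame, min_reads: int = MIN_READS) -> pd.DataFrame:
    """Drop profiles whose total read count is below min_reads."""
    return profiles.loc[profiles.sum(axis=1) >= min_reads]


def gaussian_kernel(window: int = KERNEL_WINDOW, sigma: float = KERNEL_SIGMA) -> np.ndarray:
    half = window // 2
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_profile(profile: np.ndarray) -> np.ndarray:
    """Gaussian-smooth a 60-bin profile and trim smoothing edge effects.

    Returns the central 48 bins; every retained bin has full kernel support,
    so a constant profile stays exactly constant.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape[-1] != N_BINS_RAW:
        raise ValueError(f"expected {N_BINS_RAW}-bin raw profile")
    kernel = gaussian_kernel()
    if profile.ndim == 1:
        sm = np.convolve(profile, kernel, mode="same")
        return sm[TRIM_BINS : N_BINS_RAW - TRIM_BINS]
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, profile)
    return sm[:, TRIM_BINS : N_BINS_RAW - TRIM_BINS]


def smooth_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        smooth_profile(profiles.values), index=profiles.index
    )


def average_profiles(
    profiles: pd.DataFrame | np.ndarray, mark: str = "", rtss_class: str = ""
) -> AverageProfile:
    values = np.asarray(profiles, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[0] < 1:
        raise ValueError("need at least one profile to average")
    return AverageProfile(mark, rtss_class, values.mean(axis=0), values.shape[0])


def signal_profile(
    track: SignalTrack,
    chrom: str,
    anchor: int,
    strand: str,
    bin_bp: int = BIN_BP,
    flank: int = FLANK_BP,
) -> np.ndarray:
    """Per-bin sums of a base-resolution signal track around an anchor."""
    if flank % bin_bp:
        raise ValueError("flank must be divisible by bin_bp")
    edges = np.arange(anchor - flank, anchor + flank + 1, bin_bp)
    # negative genome coordinates contribute nothing
    vals = track.window_sums(chrom, np.maximum(edges, 0))
    zero = edges[1:] <= 0
    vals[zero] = 0.0
    if strand == "-":
        vals = vals[::-1]
    return vals


def signal_profile_matrix(
    track: SignalTrack,
    catalog: list[RtssRecord],
    bin_bp: int = BIN_BP,
    flank: int = FLANK_BP,
) -> pd.DataFrame:
    rows = [
        signal_profile(track, r.chrom, r.anchor, r.strand, bin_bp, flank)
        for r in catalog
    ]
    return pd.DataFrame(np.array(rows), index=[r.id for r in catalog])
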