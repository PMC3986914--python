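"""Selection of poised RTSSs: repressed TSS clusters carrying active marks.

A repressed RTSS (zero CAGE tags in the focal cell line) is called poised
when its chromatin looks like that of other repressed-but-marked RTSSs and
clearly unlike the expressed average. The pooled procedure sums the raw
profiles of all active marks around each repressed RTSS and requires, all
conjunctively: (i) overlap with an enrichment peak of any mark, (ii) pooled
total above 1000 reads, (iii) correlation above 0.5 to the average pooled
repressed profile, and (iv) that correlation significantly larger (p <=
0.05, test for two dependent correlations) than the correlation to the
average pooled expressed profile. The per-mark alternative applies the same
criteria per active mark with a 100-read total threshold and selects RTSSs
passing in at least three marks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .overlap_index import IntervalIndex
from .profile_engine import smooth_profile
from .shape_clustering import pearson_correlation_matrix
from .types import GenomicInterval, RtssRecord

# Marks traditionally regarded as transcription-activating.
ACTIVE_MARKS = (
    "DNaseHS",
    "H2A.Z",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K27ac",
    "H3K9ac",
    "H3K36me3",
    "H3K79me2",
    "H4K20me1",
)
REPRESSIVE_MARKS = ("H3K27me3", "H3K9me3")
POL2_MARK = "PolII"


@dataclass
class PoisedCriteria:
    peak_overlap_required: bool = True
    pooled_min_reads: float = 1000.0
    min_corr_repressed: float = 0.5
    max_p: float = 0.05
    per_mark_min_reads: float = 100.0
    min_marks_passing: int = 3
    extension_bp: int = 500

    def __post_init__(self) -> None:
        if not (0 < self.max_p < 1):
            raise ValueError("max_p must be in (0,1)")
        if min(self.pooled_min_reads, self.per_mark_min_reads) <= 0:
            raise ValueError("read thresholds must be positive")


@dataclass
class PoisedResult:
    selected: list[str]
    diagnostics: pd.DataFrame
    criteria: PoisedCriteria = field(default_factory=PoisedCriteria)


def pool_active_profiles(
    per_mark_raw: dict[str, pd.DataFrame],
    ids: list[str],
    active_marks: tuple[str, ...] = ACTIVE_MARKS,
) -> pd.DataFrame:
    """Element-wise sum of raw per-mark profiles over the active panel.

    Missing marks (or ids absent from a mark's matrix) contribute zeros.
    """
    marks = [m for m in active_marks if m in per_mark_raw]
    if not marks:
        raise ValueError("no active-mark profiles available")
    n_bins = per_mark_raw[marks[0]].shape[1]
    pooled = np.zeros((len(ids), n_bins))
    for mark in marks:
        pooled += per_mark_raw[mark].reindex(ids).fillna(0.0).values
    return pd.DataFrame(pooled, index=pd.Index(ids, name="rtss_id"))


def dependent_corr_test(
    r_jk: float, r_jh: float, r_kh: float, n: int
) -> float:
    """One-sided p for H1: r_jk > r_jh, two dependent correlations sharing j.

    Williams' t (Steiger's recommended statistic) with df = n - 3:

        t = (r_jk - r_jh) * sqrt( ((n-1)(1+r_kh)) /
              ( 2((n-1)/(n-3))|R| + rbar^2 (1-r_kh)^3 ) )

    where |R| = 1 - r_jk^2 - r_jh^2 - r_kh^2 + 2 r_jk r_jh r_kh and
    rbar = (r_jk + r_jh)/2. At r_jk = r_jh, p = 0.5; swapping the two
    correlations maps p to 1 - p.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r_jk, r_jh, r_kh):
        if abs(r) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
    # tolerate float overshoot from exact self-correlations
    r_jk, r_jh, r_kh = (float(np.clip(r, -1, 1)) for r in (r_jk, r_jh, r_kh))
    det = 1 - r_jk**2 - r_jh**2 - r_kh**2 + 2 * r_jk * r_jh * r_kh
    det = max(det, 0.0)  # numerical floor; |R| >= 0 for a valid corr matrix
    rbar = (r_jk + r_jh) / 2
    denom = 2 * ((n - 1) / (n - 3)) * det + rbar**2 * (1 - r_kh) ** 3
    if denom <= 0:
        t = np.inf * np.sign(r_jk - r_jh) if r_jk != r_jh else 0.0
    else:
        t = (r_jk - r_jh) * np.sqrt((n - 1) * (1 + r_kh) / denom)
    return float(stats.t.sf(t, df=n - 3))


def reference_profiles(
    pooled_raw: pd.DataFrame,
    expressed_ids: list[str],
    repressed_ids: list[str],
    has_peak: pd.Series,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed average pooled profiles for the expressed and repressed
    reference classes, restricted to peak-overlapping members."""
    exp_ids = [i for i in expressed_ids if bool(has_peak.get(i, False))]
    rep_ids = [i for i in repressed_ids if bool(has_peak.get(i, False))]
    if not exp_ids or not rep_ids:
        raise ValueError("need peak-overlapping RTSSs in both reference classes")
    avg_expressed = smooth_profile(pooled_raw.loc[exp_ids].values.mean(axis=0))
    avg_repressed = smooth_profile(pooled_raw.loc[rep_ids].values.mean(axis=0))
    return avg_repressed, avg_expressed


def peak_overlap_flags(
    catalog: list[RtssRecord],
    peaks_by_mark: dict[str, list[GenomicInterval]],
    extension: int = 500,
    marks: tuple[str, ...] | None = None,
) -> pd.Series:
    """True for RTSSs whose extended interval overlaps any mark's peaks."""
    use = [m for m in (marks or sorted(peaks_by_mark))]
    combined: list[GenomicInterval] = []
    for m in use:
        combined.extend(peaks_by_mark.get(m, []))
    idx = IntervalIndex(combined)
    flags = {
        r.id: idx.any_overlap(
            r.chrom, max(0, r.interval.start - extension), r.interval.end + extension
        )
        for r in catalog
    }
    return pd.Series(flags)


def _criteria_frame(
    ids: list[str],
    totals: np.ndarray,
    r_rep: np.ndarray,
    r_exp: np.ndarray,
    pvals: np.ndarray,
    has_peak: np.ndarray,
    criteria: PoisedCriteria,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "total": totals,
            "r_repressed": r_rep,
            "r_expressed": r_exp,
            "p_value": pvals,
            "has_peak": has_peak,
        },
        index=pd.Index(ids, name="rtss_id"),
    )
    df["pass_peak"] = df["has_peak"] | (not criteria.peak_overlap_required)
    df["pass_total"] = df["total"] > criteria.pooled_min_reads
    df["pass_corr"] = df["r_repressed"] > criteria.min_corr_repressed
    df["pass_test"] = df["p_value"] <= criteria.max_p
    df["selected"] = df[["pass_peak", "pass_total", "pass_corr", "pass_test"]].all(
        axis=1
    )
    return df


def select_poised_pooled(
    repressed_ids: list[str],
    pooled_raw: pd.DataFrame,
    avg_repressed: np.ndarray,
    avg_expressed: np.ndarray,
    has_peak: pd.Series,
    criteria: PoisedCriteria | None = None,
) -> PoisedResult:
    """Pooled-profile poised selection over all repressed candidates.

    Totals are taken on the raw 60-bin pooled profiles; correlations on
    their smoothed 48-bin versions, consistently with clustering. n for the
    dependent-correlations test is the number of smoothed bins.
    """
    criteria = criteria or PoisedCriteria()
    raw = pooled_raw.reindex(repressed_ids).fillna(0.0)
    totals = raw.values.sum(axis=1)
    smoothed = smooth_profile(raw.values)
    n_bins = smoothed.shape[1]
    r_rep = pearson_correlation_matrix(smoothed, avg_repressed)[:, 0]
    r_exp = pearson_correlation_matrix(smoothed, avg_expressed)[:, 0]
    r_refs = float(pearson_correlation_matrix(avg_repressed, avg_expressed)[0, 0])
    pvals = np.array(
        [
            dependent_corr_test(rj, rh, r_refs, n_bins)
            for rj, rh in zip(r_rep, r_exp)
        ]
    )
    peaks = has_peak.reindex(repressed_ids).fillna(False).to_numpy(dtype=bool)
    df = _criteria_frame(repressed_ids, totals, r_rep, r_exp, pvals, peaks, criteria)
    return PoisedResult(list(df.index[df["selected"]]), df, criteria)


def select_poised_per_mark(
    repressed_ids: list[str],
    per_mark_raw: dict[str, pd.DataFrame],
    per_mark_refs: dict[str, tuple[np.ndarray, np.ndarray]],
    per_mark_has_peak: dict[str, pd.Series],
    criteria: PoisedCriteria | None = None,
    active_marks: tuple[str, ...] = ACTIVE_MARKS,
) -> PoisedResult:
    """Per-mark poised selection: all four criteria per active mark
    (100-read totals), selected iff >= min_marks_passing marks pass."""
    criteria = criteria or PoisedCriteria()
    per_mark_criteria = PoisedCriteria(
        peak_overlap_required=criteria.peak_overlap_required,
        pooled_min_reads=criteria.per_mark_min_reads,
        min_corr_repressed=criteria.min_corr_repressed,
        max_p=criteria.max_p,
        per_mark_min_reads=criteria.per_mark_min_reads,
        min_marks_passing=criteria.min_marks_passing,
        extension_bp=criteria.extension_bp,
    )
    marks = [m for m in active_marks if m in per_mark_raw and m in per_mark_refs]
    if not marks:
        raise ValueError("no usable active marks")
    n_pass = pd.Series(0, index=pd.Index(repressed_ids, name="rtss_id"))
    per_mark_flags = {}
    for mark in marks:
        avg_rep, avg_exp = per_mark_refs[mark]
        res = select_poised_pooled(
            repressed_ids,
            per_mark_raw[mark],
            avg_rep,
            avg_exp,
            per_mark_has_peak[mark],
            per_mark_criteria,
        )
        flag = res.diagnostics["selected"]
        per_mark_flags[mark] = flag
        n_pass += flag.astype(int)
    diag = pd.DataFrame(per_mark_flags)
    diag["n_marks_passing"] = n_pass
    diag["selected"] = n_pass >= criteria.min_marks_passing
    return PoisedResult(list(diag.index[diag["selected"]]), diag, criteria)


def compare_selections(a: set[str], b: set[str]) -> dict[str, float]:
    """Overlap fractions |a&b|/|a|, |a&b|/|b| and Jaccard of two selections."""
    a, b = set(a), set(b)
    inter = len(a & b)
    union = len(a | b)
    return {
        "frac_of_a": inter / len(a) if a else 0.0,
        "frac_of_b": inter / len(b) if b else 0.0,
        "jaccard": inter / union if union else 0.0,
    }


def profile_comparison_report(
    groups: dict[str, list[str]],
    profiles: pd.DataFrame,
    mark: str = "",
) -> dict[str, "np.ndarray"]:
    """Average profile of one mark for each disjoint RTSS group.

    Typical use: Pol II (or nucleosome signal) over expressed vs poised vs
    all-repressed RTSSs. Empty groups are an error; ids without a profile
    contribute zero vectors (no reads observed).
    """
    all_ids = [i for ids in groups.values() for i in ids]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("groups must be disjoint")
    out = {}
    for name, ids in groups.items():
        if not ids:
            raise ValueError(f"empty group {name!r}")
        out[name] = profiles.reindex(ids).fillna(0.0).values.mean(axis=0)
    return out
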