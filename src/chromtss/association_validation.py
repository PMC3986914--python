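"""Validation analyses: expression intra-correlation in windows around gene
TSSs, CpG-island enrichment of promoter sets, and PCA of binary term-gene
matrices.

The intra-correlation check asks whether RTSSs that share a chromatin-state
cluster also co-vary in expression across samples more than arbitrary RTSSs
in the same genomic window — the functional-coherence signature the
clustering is supposed to capture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .overlap_index import IntervalIndex
from .types import ExpressionMatrix, GenomicInterval, RtssRecord

# Window half-widths (bp) at which intra-correlations are evaluated.
DEFAULT_HALF_WIDTHS = (50, 200, 500, 1000, 5000, 10000, 50000, 150000)
PROMOTER_UPSTREAM_BP = 200
N_RANDOM_BASELINE = 100
N_PERM_CPG = 1000


@dataclass
class WindowCorrelationReport:
    window_half_width: int
    group: str
    n_pairs: int
    mean_pairwise_r: float | None


@dataclass
class CpGEnrichment:
    promoter_set: str
    observed_bp: int
    expected_bp: float
    ratio: float
    p_value: float | None = None


def transform_expression(
    counts: pd.DataFrame, method: str = "log_tpm"
) -> pd.DataFrame:
    """Expression transform used before correlation: tags-per-million then
    log(1+x) by default; 'raw' leaves counts untouched."""
    if method == "raw":
        return counts.astype(float)
    if method == "log_tpm":
        colsum = counts.sum(axis=0).replace(0, 1)
        return np.log1p(counts / colsum * 1e6)
    raise ValueError(f"unknown transform {method!r}")


def _pair_correlations(x: np.ndarray) -> np.ndarray:
    """Upper-triangle pairwise Pearson r between rows; constant rows give
    nan and are excluded by the caller via nan filtering."""
    if x.shape[0] < 2:
        return np.array([])
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    iu = np.triu_indices(x.shape[0], k=1)
    return c[iu]


def window_intra_correlation(
    expr: ExpressionMatrix,
    catalog: list[RtssRecord],
    gene_tss: pd.DataFrame,
    rtss_subset: set[str] | None = None,
    half_widths: tuple[int, ...] = DEFAULT_HALF_WIDTHS,
    transform: str = "log_tpm",
    group: str = "all",
) -> list[WindowCorrelationReport]:
    """Mean pairwise expression correlation of RTSSs near gene TSSs.

    For each gene TSS anchor and half-width W, members are the RTSSs (of
    the subset, or all) whose anchor lies within [TSS-W, TSS+W]; pair
    correlations are pooled across anchors before averaging (grand mean
    over pairs).
    """
    if list(half_widths) != sorted(half_widths) or min(half_widths) <= 0:
        raise ValueError("half_widths must be positive and sorted")
    x = transform_expression(expr.counts, transform)
    keep = [
        r
        for r in catalog
        if r.id in x.index and (rtss_subset is None or r.id in rtss_subset)
    ]
    anchors_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for r in keep:
        anchors_by_chrom.setdefault(r.chrom, []).append((r.anchor, r.id))
    for chrom in anchors_by_chrom:
        anchors_by_chrom[chrom].sort()

    reports = []
    for w in half_widths:
        pooled: list[np.ndarray] = []
        for g in gene_tss.itertuples():
            members = anchors_by_chrom.get(g.chrom, [])
            if not members:
                continue
            pos = np.array([m[0] for m in members])
            lo = np.searchsorted(pos, g.tss - w, side="left")
            hi = np.searchsorted(pos, g.tss + w, side="right")
            ids = [members[i][1] for i in range(lo, hi)]
            if len(ids) >= 2:
                pooled.append(_pair_correlations(x.loc[ids].values))
        rs = np.concatenate(pooled) if pooled else np.array([])
        rs = rs[~np.isnan(rs)]
        reports.append(
            WindowCorrelationReport(
                w, group, len(rs), float(rs.mean()) if len(rs) else None
            )
        )
    return reports


def random_baseline_correlation(
    expr: ExpressionMatrix,
    n_sample: int = N_RANDOM_BASELINE,
    seed: int | None = None,
    transform: str = "log_tpm",
) -> float:
    """Mean of all pairwise correlations among n randomly drawn RTSSs."""
    if len(expr.rtss_ids) < n_sample:
        raise ValueError("catalog smaller than requested sample")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(expr.rtss_ids), size=n_sample, replace=False)
    x = transform_expression(expr.counts, transform).values[np.sort(idx)]
    rs = _pair_correlations(x)
    rs = rs[~np.isnan(rs)]
    return float(rs.mean()) if len(rs) else float("nan")


def promoter_regions(
    catalog: list[RtssRecord],
    upstream_bp: int = PROMOTER_UPSTREAM_BP,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """The region upstream of each RTSS: [start-u, start) on +, [end, end+u)
    on -; clipped at chromosome bounds, empty results dropped."""
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be positive")
    out = []
    for r in catalog:
        if r.strand == "+":
            s, e = max(0, r.interval.start - upstream_bp), r.interval.start
        else:
            s, e = r.interval.end, r.interval.end + upstream_bp
        if chrom_sizes and r.chrom in chrom_sizes:
            e = min(e, chrom_sizes[r.chrom])
        if s < e:
            out.append(GenomicInterval(r.chrom, s, e, r.strand))
    return out


def _overlap_per_interval(
    intervals: list[GenomicInterval], index: IntervalIndex
) -> tuple[np.ndarray, np.ndarray]:
    ov = np.array([index.bp_overlap(p.chrom, p.start, p.end) for p in intervals])
    ln = np.array([len(p) for p in intervals])
    return ov, ln


def cpg_enrichment(
    promoters: list[GenomicInterval],
    cpg_islands: list[GenomicInterval] | IntervalIndex,
    background_promoters: list[GenomicInterval],
    label: str = "",
) -> CpGEnrichment:
    """Observed vs expected bp overlap of a promoter set with CpG islands.

    Expected = promoter bp x (background overlap fraction); the ratio is
    the enrichment factor relative to all promoters.
    """
    if not promoters or not background_promoters:
        raise ValueError("promoter sets must be nonempty")
    index = (
        cpg_islands
        if isinstance(cpg_islands, IntervalIndex)
        else IntervalIndex(cpg_islands)
    )
    ov, ln = _overlap_per_interval(promoters, index)
    bg_ov, bg_ln = _overlap_per_interval(background_promoters, index)
    bg_fraction = bg_ov.sum() / bg_ln.sum()
    expected = float(ln.sum() * bg_fraction)
    if expected == 0:
        raise ValueError("expected overlap is zero (no CpG signal in background)")
    observed = int(ov.sum())
    return CpGEnrichment(label, observed, expected, observed / expected)


def cpg_case_control_test(
    case_promoters: list[GenomicInterval],
    control_promoters: list[GenomicInterval],
    cpg_islands: list[GenomicInterval] | IntervalIndex,
    n_perm: int = N_PERM_CPG,
    seed: int | None = None,
) -> float:
    """Monte-Carlo p for: case promoters overlap CpG islands more than
    controls. Statistic = difference of overlap fractions; case/control
    labels are permuted across the combined promoter list preserving set
    sizes; add-one one-sided p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not case_promoters or not control_promoters:
        raise ValueError("both promoter sets must be nonempty")
    index = (
        cpg_islands
        if isinstance(cpg_islands, IntervalIndex)
        else IntervalIndex(cpg_islands)
    )
    all_proms = list(case_promoters) + list(control_promoters)
    ov, ln = _overlap_per_interval(all_proms, index)
    n_case = len(case_promoters)
    is_case = np.zeros(len(all_proms), dtype=bool)
    is_case[:n_case] = True

    def stat(mask: np.ndarray) -> float:
        return ov[mask].sum() / ln[mask].sum() - ov[~mask].sum() / ln[~mask].sum()

    observed = stat(is_case)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = np.zeros(len(all_proms), dtype=bool)
        perm[rng.choice(len(all_proms), size=n_case, replace=False)] = True
        exceed += stat(perm) >= observed
    return (1 + exceed) / (1 + n_perm)


def term_matrix_pca(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a binary clusters x genes term-membership matrix.

    Columns are centered (not scaled); returns scores on the first two
    components (rows = clusters) and their explained-variance ratios. Sign
    convention: the largest-magnitude loading of each component is positive.
    A zero-variance matrix yields all-zero scores.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix")
    x = matrix.values.astype(float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = (s**2).sum()
    if total == 0:
        scores = np.zeros((matrix.shape[0], 2))
        evr = np.zeros(2)
    else:
        for c in range(min(2, vt.shape[0])):
            lead = np.argmax(np.abs(vt[c]))
            if vt[c, lead] < 0:
                vt[c] *= -1
                u[:, c] *= -1
        scores = (u[:, :2] * s[:2]) if len(s) >= 2 else np.pad(
            u[:, :1] * s[:1], ((0, 0), (0, 1))
        )
        evr = (s[:2] ** 2) / total
    return (
        pd.DataFrame(scores, index=matrix.index, columns=["PC1", "PC2"]),
        evr,
    )
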