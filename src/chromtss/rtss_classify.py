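"""Classify RTSSs by expression status and genomic location.

Expression is a three-way partition of a focal sample's CAGE tag counts:
zero tags = repressed, at least `threshold` tags = expressed, anything in
between = intermediate (excluded from both downstream sets). Location is a
four-way partition against gene annotations with precedence
annotated > proximal > intragenic > intergenic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .overlap_index import IntervalIndex
from .types import ExpressionMatrix, GenomicInterval, RtssRecord

EXPRESSED = "expressed"
REPRESSED = "repressed"
INTERMEDIATE = "intermediate"

ANNOTATED = "annotated"
PROXIMAL = "proximal"
INTRAGENIC = "intragenic"
INTERGENIC = "intergenic"

DEFAULT_TAG_THRESHOLD = 5
PROXIMAL_BP = 150
ISOLATION_GAP_BP = 2000


def classify_expression(
    expr: ExpressionMatrix, focal_sample: str, threshold: int = DEFAULT_TAG_THRESHOLD
) -> pd.Series:
    """Map each RTSS to expressed / repressed / intermediate.

    Repressed means exactly zero tags in the focal sample; expressed means
    at least `threshold` tags; intermediate covers 0 < count < threshold.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = expr.sample(focal_sample)
    out = pd.Series(INTERMEDIATE, index=counts.index, name="expression_class")
    out[counts == 0] = REPRESSED
    out[counts >= threshold] = EXPRESSED
    return out


def scaled_threshold(
    base_threshold: int, library_tags: int, reference_tags: int = 30_000_000
) -> int:
    """Library-size-scaled tag threshold (floor 1), e.g. 5 -> 3 for a
    shallow ~10M-tag library against a ~30M reference."""
    return max(1, round(base_threshold * library_tags / reference_tags))


class LocationClassifier:
    """Single-record location classifier against a fixed gene annotation.

    annotated: the RTSS interval contains an annotated gene TSS base of
    matching strand. proximal: the RTSS anchor lies within +/- proximal_bp
    of a same-strand gene TSS. intragenic: any overlap with any gene span,
    strand-agnostic. intergenic otherwise. Precedence in that order.
    """

    def __init__(self, genes: pd.DataFrame, proximal_bp: int = PROXIMAL_BP):
        self.proximal_bp = proximal_bp
        self._tss_by = {
            (chrom, strand): np.sort(grp["tss"].to_numpy())
            for (chrom, strand), grp in genes.groupby(["chrom", "strand"])
        }
        self._gene_index = IntervalIndex(
            [
                GenomicInterval(row.chrom, int(row.txStart), int(row.txEnd), row.strand)
                for row in genes.itertuples()
            ]
        )

    def classify(self, r: RtssRecord) -> str:
        tss = self._tss_by.get((r.chrom, r.strand), np.array([], dtype=np.int64))
        lo = np.searchsorted(tss, r.interval.start, side="left")
        hi = np.searchsorted(tss, r.interval.end - 1, side="right")
        if hi > lo:  # same-strand TSS base inside [start, end)
            return ANNOTATED
        i = np.searchsorted(tss, r.anchor)
        near = min(
            (abs(int(t) - r.anchor) for t in tss[max(0, i - 1) : i + 1]),
            default=None,
        )
        if near is not None and near <= self.proximal_bp:
            return PROXIMAL
        if self._gene_index.any_overlap(r.chrom, r.interval.start, r.interval.end):
            return INTRAGENIC
        return INTERGENIC


def classify_location(
    catalog: list[RtssRecord],
    genes: pd.DataFrame,
    proximal_bp: int = PROXIMAL_BP,
) -> pd.Series:
    """Map each RTSS to annotated / proximal / intragenic / intergenic."""
    clf = LocationClassifier(genes, proximal_bp)
    out = {r.id: clf.classify(r) for r in catalog}
    return pd.Series(out, name="location_class").reindex([r.id for r in catalog])


def find_isolated(
    catalog: list[RtssRecord], min_gap: int = ISOLATION_GAP_BP
) -> set[str]:
    """RTSSs whose edge-to-edge distance to every other RTSS is >= min_gap.

    The bound is inclusive; overlapping RTSSs have distance 0. An RTSS
    alone on its chromosome is isolated.
    """
    isolated: set[str] = set()
    by_chrom: dict[str, list[RtssRecord]] = {}
    for r in catalog:
        by_chrom.setdefault(r.chrom, []).append(r)
    for rs in by_chrom.values():
        starts = np.array([r.interval.start for r in rs])
        ends = np.array([r.interval.end for r in rs])
        # gap(i,j) = max(s_j - e_i, s_i - e_j, 0): edge distance, 0 if overlapping
        gaps = np.maximum(
            starts[None, :] - ends[:, None], starts[:, None] - ends[None, :]
        )
        np.fill_diagonal(gaps, np.iinfo(np.int64).max)
        nearest = np.maximum(gaps, 0).min(axis=1)
        for r, g in zip(rs, nearest):
            if g >= min_gap:
                isolated.add(r.id)
    return isolated


def filter_unmappable(
    catalog: list[RtssRecord], excludable: list[GenomicInterval]
) -> list[RtssRecord]:
    """Drop every RTSS with any bp overlap with an excludable interval."""
    if not excludable:
        return list(catalog)
    index = IntervalIndex(excludable)
    return [
        r
        for r in catalog
        if not index.any_overlap(r.chrom, r.interval.start, r.interval.end)
    ]


def classification_table(
    catalog: list[RtssRecord],
    expression: pd.Series,
    location: pd.Series,
    isolated: set[str],
) -> pd.DataFrame:
    ids = [r.id for r in catalog]
    return pd.DataFrame(
        {
            "expression_class": expression.reindex(ids),
            "location_class": location.reindex(ids),
            "isolated": [rid in isolated for rid in ids],
        },
        index=pd.Index(ids, name="rtss_id"),
    )
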