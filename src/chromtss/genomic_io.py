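"""Readers and writers for the interval, tag, signal and matrix formats.

Everything is normalized to 0-based half-open coordinates on read; wiggle
(1-based) input is converted. Peak sets are never merged on read — merging
is an explicit downstream choice.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GenomicInterval, ReadStartSet, RtssRecord, SignalTrack

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed line in a genomic text format; carries the line number."""


def _iter_data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_rtss_catalog(path) -> list[RtssRecord]:
    """Read a BED6-like RTSS catalog (chrom start end id score strand)."""
    records: list[RtssRecord] = []
    seen: set[str] = set()
    for lineno, line in _iter_data_lines(path):
        fields = line.split()
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
        chrom, start, end, rid, _score, strand = fields[:6]
        try:
            iv = GenomicInterval(chrom, int(start), int(end), strand)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: RTSS strand must be + or -")
        if rid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate RTSS id {rid!r}")
        seen.add(rid)
        records.append(RtssRecord(rid, iv))
    if not records:
        logger.warning("empty RTSS catalog: %s", path)
    return records


def write_rtss_catalog(records: list[RtssRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.id}\t0\t{r.strand}\n"
            )


def read_peaks(path) -> list[GenomicInterval]:
    """Read broadPeak/narrowPeak/BED intervals; extra columns ignored.

    Intervals are returned sorted by (chrom, start); overlapping peaks are
    retained as-is.
    """
    peaks: list[GenomicInterval] = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start >= end")
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        peaks.append(GenomicInterval(chrom, start, end, strand))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def write_peaks(peaks: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t.\t0\t{p.strand}\n")


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Alias used for CpG islands and excludable-region BED files."""
    return read_peaks(path)


def read_tags(path, mark: str) -> ReadStartSet:
    """Read a BED6 tag file of mapped-read start positions.

    The 5' start position of each record is taken: the BED start for +
    strand reads and end-1 for - strand reads.
    """
    chroms: list[str] = []
    positions: list[int] = []
    strands: list[str] = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split()
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns for tags")
        chrom, start, end, _name, _score, strand = fields[:6]
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: tag strand must be + or -")
        start_i, end_i = int(start), int(end)
        chroms.append(chrom)
        positions.append(start_i if strand == "+" else end_i - 1)
        strands.append(strand)
    return ReadStartSet(
        mark,
        np.asarray(chroms, dtype=object),
        np.asarray(positions, dtype=np.int64),
        np.asarray(strands, dtype=object),
    )


def write_tags(reads: ReadStartSet, path) -> None:
    """Write a ReadStartSet as 1-bp BED6 records (position = 5' start)."""
    with open(path, "w") as fh:
        for chrom, pos, strand in zip(reads.chroms, reads.positions, reads.strands):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t0\t{strand}\n")


def read_tags_from_alignment(path, mark: str) -> ReadStartSet:
    """Optional sugar: reduce a SAM/BAM alignment file to 5' tag records."""
    import pysam  # local import: pysam only needed for this path

    chroms, positions, strands = [], [], []
    with pysam.AlignmentFile(str(path)) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            chroms.append(aln.reference_name)
            if aln.is_reverse:
                positions.append(aln.reference_end - 1)
                strands.append("-")
            else:
                positions.append(aln.reference_start)
                strands.append("+")
    return ReadStartSet(
        mark,
        np.asarray(chroms, dtype=object),
        np.asarray(positions, dtype=np.int64),
        np.asarray(strands, dtype=object),
    )


def read_signal(path) -> SignalTrack:
    """Read a bedGraph or fixedStep/variableStep wiggle file.

    Wiggle coordinates (1-based) are converted to 0-based half-open.
    Overlapping bedGraph intervals are an error.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    mode = "bedgraph"
    chrom = None
    step = span = 1
    next_pos = 0
    for lineno, line in _iter_data_lines(path):
        fields = line.split()
        if fields[0] == "fixedStep":
            kv = dict(f.split("=", 1) for f in fields[1:])
            mode, chrom = "fixed", kv["chrom"]
            next_pos = int(kv["start"]) - 1  # wiggle is 1-based
            step = int(kv.get("step", 1))
            span = int(kv.get("span", 1))
            continue
        if fields[0] == "variableStep":
            kv = dict(f.split("=", 1) for f in fields[1:])
            mode, chrom = "variable", kv["chrom"]
            span = int(kv.get("span", 1))
            continue
        if mode == "bedgraph":
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            per_chrom.setdefault(c, []).append((s, e, v))
        elif mode == "fixed":
            v = float(fields[0])
            per_chrom.setdefault(chrom, []).append((next_pos, next_pos + span, v))
            next_pos += step
        else:  # variable
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'pos value'")
            pos = int(fields[0]) - 1
            per_chrom.setdefault(chrom, []).append((pos, pos + span, float(fields[1])))

    track = SignalTrack()
    for c, rows in per_chrom.items():
        arr = np.array(rows, dtype=float)
        track.add_chrom(
            c, arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2]
        )
    return track


def write_signal_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            starts, ends, values = track.data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_genes(path) -> pd.DataFrame:
    """Read a refFlat-like gene TSV: gene_id, chrom, strand, txStart, txEnd.

    Returns a DataFrame with an added ``tss`` column: txStart on + genes and
    txEnd-1 on - genes (the 5'-most transcribed base).
    """
    genes = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["gene_id", "chrom", "strand", "txStart", "txEnd"],
        dtype={"gene_id": str, "chrom": str, "strand": str},
    )
    if (genes["txStart"] >= genes["txEnd"]).any():
        raise ParseError(f"{path}: gene with txStart >= txEnd")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ParseError(f"{path}: gene strand must be + or -")
    genes["tss"] = np.where(genes["strand"] == "+", genes["txStart"], genes["txEnd"] - 1)
    return genes


def write_genes(genes: pd.DataFrame, path) -> None:
    genes[["gene_id", "chrom", "strand", "txStart", "txEnd"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV expression matrix; header row = sample ids, first column = RTSS id."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(df)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.counts.to_csv(path, sep="\t", index_label="rtss_id")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    for _lineno, line in _iter_data_lines(path):
        chrom, size = line.split()[:2]
        sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
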