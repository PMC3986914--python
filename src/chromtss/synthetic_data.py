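"""Synthetic CAGE/ChIP-seq dataset generator with planted ground truth.

Emulates the statistical structure the analysis assumes so every stage is
testable without external downloads: an RTSS catalog with expressed /
repressed / intermediate tag counts over S pseudo-samples, per-mark ChIP
reads drawn from a library of planted profile shapes, combinatorial
metacluster archetypes over the mark panel, a planted poised subset
(zero focal expression, active marks + Pol II, retained central
nucleosome), correlated expression neighborhoods, and CpG islands covering
a subset of promoters.

Reads are emitted UN-shifted (+ strand reads moved -100 bp, - strand
+100 bp, mimicking 5' read starts of ~200 bp fragments) so the pipeline's
shift step is exercised rather than bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rtss_classify as rc
from .poised_selection import ACTIVE_MARKS, POL2_MARK
from .profile_engine import BIN_BP, FLANK_BP, N_BINS_RAW, SHIFT_BP
from .types import (
    ExpressionMatrix,
    GenomicInterval,
    ReadStartSet,
    RtssRecord,
    SignalTrack,
)

# ---------------------------------------------------------------- shapes


@dataclass(frozen=True)
class ShapeTemplate:
    """A normalized 60-bin profile shape used to plant ChIP read patterns."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_BINS_RAW,):
            raise ValueError("template must have 60 bins")
        if (v < 0).any() or not np.isclose(v.sum(), 1.0):
            raise ValueError("template must be non-negative and sum to 1")


def _gauss(center: float, sigma: float) -> np.ndarray:
    x = np.arange(N_BINS_RAW)
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def builtin_shape_library() -> list[ShapeTemplate]:
    """The built-in shape families seen around TSSs.

    symmetric_dip: flanking peaks with a depleted center (the nucleosome-
    free region at active TSSs); center_peak: a single well-positioned
    central nucleosome / stalled Pol II peak; downstream_ramp / upstream_
    ramp: signal rising in (or against) the transcript direction;
    flat_enriched: uniform enrichment.
    """
    center = (N_BINS_RAW - 1) / 2  # 29.5: the window midpoint between bins 29/30
    dip = _gauss(center - 4.5, 3.0) + _gauss(center + 4.5, 3.0)
    peak = _gauss(center, 3.0)
    ramp = np.linspace(0.05, 1.0, N_BINS_RAW)
    flat = np.ones(N_BINS_RAW)
    lib = [
        ShapeTemplate("symmetric_dip", dip / dip.sum()),
        ShapeTemplate("center_peak", peak / peak.sum()),
        ShapeTemplate("downstream_ramp", ramp / ramp.sum()),
        ShapeTemplate("upstream_ramp", ramp[::-1] / ramp.sum()),
        ShapeTemplate("flat_enriched", flat / flat.sum()),
    ]
    return lib


SHAPE_BY_NAME = {t.name: t for t in builtin_shape_library()}
ABSENT = "absent"  # pseudo-template: the mark is not enriched at this RTSS

# ------------------------------------------------------------- archetypes


def default_archetypes(
    marks: list[str], n_archetypes: int = 10
) -> dict[int, dict[str, str]]:
    """Deterministic, mutually distinct metacluster archetypes.

    Each archetype maps every mark to one of four shapes or to ABSENT;
    signatures differ between any two archetypes, which is what level-2
    clustering is asked to recover.
    """
    # expressed TSSs show the central dip, ramps or flat enrichment; the
    # no-dip center peak is reserved for the poised/repressed signature
    choices = ["symmetric_dip", "downstream_ramp", "upstream_ramp", "flat_enriched", ABSENT]
    out: dict[int, dict[str, str]] = {}
    for a in range(n_archetypes):
        stride = 1 + a // len(choices)
        out[a] = {
            m: choices[(a + stride * j) % len(choices)] for j, m in enumerate(marks)
        }
    sigs = {tuple(v[m] for m in marks) for v in out.values()}
    if len(sigs) != n_archetypes:
        raise ValueError("archetype signatures collide; use fewer archetypes")
    return out


# ------------------------------------------------------------------ truth


@dataclass
class PlantedTruth:
    """Ground truth for recovery tests.

    table columns: expression_class, location_class, metacluster (-1 when
    none), poised (bool). archetypes: metacluster -> mark -> template name.
    """

    table: pd.DataFrame
    archetypes: dict[int, dict[str, str]]

    def __post_init__(self) -> None:
        t = self.table
        bad = t["poised"] & (t["expression_class"] != rc.REPRESSED)
        if bad.any():
            raise ValueError("poised implies repressed")
        bad = (t["metacluster"] >= 0) & (t["expression_class"] != rc.EXPRESSED)
        if bad.any():
            raise ValueError("metacluster label implies expressed")

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="rtss_id")

    @classmethod
    def read_tsv(cls, path, archetypes: dict | None = None) -> "PlantedTruth":
        t = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        t["poised"] = t["poised"].astype(bool)
        return cls(t, archetypes or {})


# ----------------------------------------------------------------- genome

DEFAULT_GENE_LENGTH = (2000, 10000)
GENE_MIN_SEPARATION = 400


def generate_genome(
    n_chroms: int,
    chrom_length: int,
    n_genes: int,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Uniformly place non-overlapping genes of random strand.

    Returns (genes DataFrame with gene_id/chrom/strand/txStart/txEnd/tss,
    chromosome sizes). Errors if the requested density is infeasible.
    """
    rng = np.random.default_rng(seed)
    sizes = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    if n_genes == 0:
        genes = pd.DataFrame(
            columns=["gene_id", "chrom", "strand", "txStart", "txEnd", "tss"]
        )
        return genes, sizes
    per_chrom = np.full(n_chroms, n_genes // n_chroms)
    per_chrom[: n_genes % n_chroms] += 1
    rows = []
    gid = 0
    for ci, chrom in enumerate(sizes):
        m = int(per_chrom[ci])
        if m == 0:
            continue
        lengths = rng.integers(DEFAULT_GENE_LENGTH[0], DEFAULT_GENE_LENGTH[1] + 1, m)
        occupied = int(lengths.sum()) + GENE_MIN_SEPARATION * m
        free = chrom_length - occupied
        if free < 0:
            raise ValueError(
                f"cannot place {m} genes of total span {occupied} on {chrom_length} bp"
            )
        # sorted uniform offsets into the free space -> non-overlapping spans
        offsets = np.sort(rng.integers(0, free + 1, m))
        cursor = np.concatenate(
            [[0], np.cumsum(lengths[:-1] + GENE_MIN_SEPARATION)]
        )
        starts = offsets + cursor
        strands = rng.choice(["+", "-"], m)
        for s, ln, st in zip(starts, lengths, strands):
            rows.append((f"g{gid}", chrom, st, int(s), int(s + ln)))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "txStart", "txEnd"])
    genes["tss"] = np.where(genes["strand"] == "+", genes["txStart"], genes["txEnd"] - 1)
    return genes, sizes


# ------------------------------------------------------------- RTSS + expr

DEFAULT_CLASS_FRACTIONS: dict[tuple[str, str], float] = {
    (rc.EXPRESSED, rc.ANNOTATED): 0.15,
    (rc.EXPRESSED, rc.PROXIMAL): 0.05,
    (rc.EXPRESSED, rc.INTRAGENIC): 0.10,
    (rc.EXPRESSED, rc.INTERGENIC): 0.10,
    (rc.REPRESSED, rc.ANNOTATED): 0.04,
    (rc.REPRESSED, rc.PROXIMAL): 0.02,
    (rc.REPRESSED, rc.INTRAGENIC): 0.22,
    (rc.REPRESSED, rc.INTERGENIC): 0.22,
    (rc.INTERMEDIATE, rc.INTRAGENIC): 0.05,
    (rc.INTERMEDIATE, rc.INTERGENIC): 0.05,
}

RTSS_WIDTH = (60, 140)


class _EnrichedRegistry:
    """Anchors of planted-enriched RTSSs; enforces a minimum separation so
    profile windows of differently-labelled enriched loci never collide
    (real promoters crowd RTSSs that then share one chromatin state; per-
    RTSS planted shapes require identifiable windows instead)."""

    def __init__(self, min_sep: int):
        import bisect

        self._bisect = bisect
        self.min_sep = min_sep
        self._anchors: dict[str, list[int]] = {}

    def clear_of(self, chrom: str, anchor: int) -> bool:
        arr = self._anchors.get(chrom, [])
        i = self._bisect.bisect_left(arr, anchor)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(arr[j] - anchor) < self.min_sep:
                return False
        return True

    def add(self, chrom: str, anchor: int) -> None:
        arr = self._anchors.setdefault(chrom, [])
        self._bisect.insort(arr, anchor)


def _place_rtss(
    loc_class: str,
    genes: pd.DataFrame,
    sizes: dict[str, int],
    rng: np.random.Generator,
    clf: rc.LocationClassifier,
    enriched: bool = False,
    registry: _EnrichedRegistry | None = None,
) -> GenomicInterval:
    chroms = list(sizes)
    for _ in range(500):
        w = int(rng.integers(*RTSS_WIDTH))
        if loc_class == rc.ANNOTATED and len(genes):
            g = genes.iloc[int(rng.integers(len(genes)))]
            start = int(g.tss) - w // 2
            iv = GenomicInterval(g.chrom, max(0, start), max(0, start) + w, g.strand)
        elif loc_class == rc.PROXIMAL and len(genes):
            g = genes.iloc[int(rng.integers(len(genes)))]
            off = int(rng.integers(w // 2 + 5, 150)) * (1 if rng.random() < 0.5 else -1)
            anchor = int(g.tss) + off
            start = anchor - w // 2
            if start < 0:
                continue
            iv = GenomicInterval(g.chrom, start, start + w, g.strand)
        elif loc_class == rc.INTRAGENIC and len(genes):
            g = genes.iloc[int(rng.integers(len(genes)))]
            lo, hi = int(g.txStart) + 400, int(g.txEnd) - 400 - w
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            iv = GenomicInterval(
                g.chrom, start, start + w, "+" if rng.random() < 0.5 else "-"
            )
        else:  # intergenic
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, sizes[chrom] - w))
            iv = GenomicInterval(
                chrom, start, start + w, "+" if rng.random() < 0.5 else "-"
            )
        # verify against the actual classification rule (rejection sampling)
        probe = RtssRecord("probe", iv)
        if clf.classify(probe) != loc_class:
            continue
        if enriched and registry is not None:
            anchor = (iv.start + iv.end) // 2
            if not registry.clear_of(iv.chrom, anchor):
                continue
            registry.add(iv.chrom, anchor)
        return iv
    raise RuntimeError(f"could not place an RTSS of class {loc_class!r}")


@dataclass
class SyntheticDataset:
    catalog: list[RtssRecord]
    expression: ExpressionMatrix
    truth: PlantedTruth
    genes: pd.DataFrame
    chrom_sizes: dict[str, int]
    reads: dict[str, ReadStartSet] = field(default_factory=dict)
    peaks: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    nucleosome: SignalTrack | None = None
    cpg_islands: list[GenomicInterval] = field(default_factory=list)
    excludable: list[GenomicInterval] = field(default_factory=list)
    focal_sample: str = "focal"
    marks: list[str] = field(default_factory=list)


def generate_rtss_set(
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    n_rtss: int,
    S: int,
    seed: int | None = None,
    class_fractions: dict[tuple[str, str], float] | None = None,
    threshold: int = rc.DEFAULT_TAG_THRESHOLD,
    expressed_mean: float = 50.0,
    repressed_mean: float = 0.5,
    dispersion: float = 0.3,
    neighborhood_sd: float = 0.6,
    neighborhood_bp: int = 50_000,
    cluster_sd: float = 0.4,
    poised_fraction: float = 0.10,
    n_archetypes: int = 10,
    marks: list[str] | None = None,
) -> tuple[list[RtssRecord], ExpressionMatrix, PlantedTruth]:
    """RTSS catalog + expression matrix + planted truth.

    Counts follow a negative binomial (CAGE counts are overdispersed);
    class means differ by orders of magnitude. Focal-sample counts are
    coerced to respect the planted class exactly (0 / >= threshold /
    in between). Two latent log-activity factors induce correlation:
    one shared by RTSSs within `neighborhood_bp` of a common anchor gene,
    one shared by RTSSs of the same planted metacluster.
    """
    if S < 2:
        raise ValueError("need S >= 2 samples (correlation undefined otherwise)")
    fractions = class_fractions or DEFAULT_CLASS_FRACTIONS
    fr = np.array(list(fractions.values()), dtype=float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts_per_class = rng.multinomial(n_rtss, fr)
    class_list: list[tuple[str, str]] = []
    for (cls, n) in zip(fractions, counts_per_class):
        class_list.extend([cls] * int(n))

    mark_list = list(marks) if marks else [f"mark{i}" for i in range(6)]
    archetypes = default_archetypes(mark_list, n_archetypes)

    # labels first: metacluster archetype per expressed RTSS, poised flags
    # on a random subset of repressed ones; enriched = either of those
    metas = np.full(len(class_list), -1)
    for i, (expr_cls, _loc) in enumerate(class_list):
        if expr_cls == rc.EXPRESSED:
            metas[i] = int(rng.integers(n_archetypes))
    rep_idx = np.array(
        [i for i, (c, _l) in enumerate(class_list) if c == rc.REPRESSED], dtype=int
    )
    poised = np.zeros(len(class_list), dtype=bool)
    n_poised = int(round(poised_fraction * len(rep_idx)))
    if n_poised:
        chosen = rng.choice(len(rep_idx), size=n_poised, replace=False)
        poised[rep_idx[np.sort(chosen)]] = True

    clf = rc.LocationClassifier(genes)
    registry = _EnrichedRegistry(min_sep=2 * FLANK_BP)
    records: list[RtssRecord] = []
    rows = []
    for i, (expr_cls, loc_cls) in enumerate(class_list):
        rid = f"r{i:05d}"
        iv = _place_rtss(
            loc_cls,
            genes,
            chrom_sizes,
            rng,
            clf,
            enriched=bool(metas[i] >= 0 or poised[i]),
            registry=registry,
        )
        records.append(RtssRecord(rid, iv))
        rows.append((rid, expr_cls, loc_cls, int(metas[i]), bool(poised[i])))
    truth_table = pd.DataFrame(
        rows,
        columns=["rtss_id", "expression_class", "location_class", "metacluster", "poised"],
    ).set_index("rtss_id")

    # latent factors -----------------------------------------------------
    tss_sorted = {
        chrom: np.sort(grp["tss"].to_numpy())
        for chrom, grp in genes.groupby("chrom")
    }
    hood_keys: list[tuple[str, int] | None] = []
    for r in records:
        tss = tss_sorted.get(r.chrom)
        key = None
        if tss is not None and len(tss):
            j = int(np.searchsorted(tss, r.anchor))
            best, bestd = -1, neighborhood_bp + 1
            for jj in (j - 1, j):
                if 0 <= jj < len(tss):
                    d = abs(int(tss[jj]) - r.anchor)
                    if d < bestd:
                        best, bestd = jj, d
            if best >= 0 and bestd <= neighborhood_bp:
                key = (r.chrom, int(tss[best]))
        hood_keys.append(key)

    hood_ids = {
        h: k for k, h in enumerate(sorted({k for k in hood_keys if k is not None}))
    }
    z_hood = rng.normal(0.0, neighborhood_sd, size=(len(hood_ids), S))
    z_meta = rng.normal(0.0, cluster_sd, size=(n_archetypes, S))

    base_log = np.empty(len(records))
    for i, rid in enumerate(truth_table.index):
        cls = truth_table.loc[rid, "expression_class"]
        if cls == rc.EXPRESSED:
            base_log[i] = np.log(expressed_mean)
        elif cls == rc.INTERMEDIATE:
            base_log[i] = np.log(max(1.0, threshold / 2))
        else:
            base_log[i] = np.log(repressed_mean)

    log_mu = np.tile(base_log[:, None], (1, S))
    for i in range(len(records)):
        if hood_keys[i] is not None:
            log_mu[i] += z_hood[hood_ids[hood_keys[i]]]
        m = truth_table.iloc[i]["metacluster"]
        if m >= 0:
            log_mu[i] += z_meta[int(m)]
    mu = np.exp(log_mu)
    size = 1.0 / dispersion
    counts = rng.negative_binomial(size, size / (size + mu))

    # coerce the focal sample to the planted class
    focal = counts[:, 0]
    for i, rid in enumerate(truth_table.index):
        cls = truth_table.loc[rid, "expression_class"]
        if cls == rc.REPRESSED:
            focal[i] = 0
        elif cls == rc.EXPRESSED:
            focal[i] = max(focal[i], threshold)
        else:
            focal[i] = int(np.clip(focal[i], 1, threshold - 1))
    counts[:, 0] = focal

    sample_ids = ["focal"] + [f"s{j}" for j in range(1, S)]
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=truth_table.index, columns=sample_ids)
    )
    return records, expr, PlantedTruth(truth_table, archetypes)


# ------------------------------------------------------------- ChIP reads

POISED_ACTIVE_SCALE = 0.8
POISED_POL2_SCALE = 0.5
EXPRESSED_POL2_SCALE = 1.0


def _enrichment_plan(
    truth: PlantedTruth, marks: list[str], active_marks: tuple[str, ...]
) -> dict[str, dict[str, tuple[str, float]]]:
    """mark -> rtss_id -> (template name, depth scale)."""
    plan: dict[str, dict[str, tuple[str, float]]] = {m: {} for m in marks}
    actives = [m for m in marks if m in active_marks or m.startswith("mark")]
    for rid, row in truth.table.iterrows():
        if row["metacluster"] >= 0:
            arch = truth.archetypes[int(row["metacluster"])]
            for m in marks:
                if m == POL2_MARK:
                    plan[m][rid] = ("center_peak", EXPRESSED_POL2_SCALE)
                    continue
                tmpl = arch.get(m, ABSENT)
                if tmpl != ABSENT:
                    plan[m][rid] = (tmpl, 1.0)
        elif row["poised"]:
            for m in marks:
                if m == POL2_MARK:
                    plan[m][rid] = ("center_peak", POISED_POL2_SCALE)
                elif m in actives:
                    plan[m][rid] = ("center_peak", POISED_ACTIVE_SCALE)
    return plan


def generate_chip_reads(
    truth: PlantedTruth,
    catalog: list[RtssRecord],
    marks: list[str],
    chrom_sizes: dict[str, int],
    depth: float = 500.0,
    noise_rate: float = 0.2,
    seed: int | None = None,
    active_marks: tuple[str, ...] = ACTIVE_MARKS,
) -> tuple[dict[str, ReadStartSet], dict[str, list[GenomicInterval]]]:
    """Per-mark read sets and enrichment peaks for the planted structure.

    For every enriched RTSS, Poisson(depth x scale) reads fall
    multinomially over the 60 template bins of the oriented +/-3 kbp
    window, jittered within bins; strands 50/50; positions are then
    un-shifted by -/+100 bp so the pipeline's shift step re-centers them.
    Uniform background reads are added at `noise_rate` per kbp. A peak is
    emitted over every enriched window.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    known = set(ACTIVE_MARKS) | {POL2_MARK, "H3K27me3", "H3K9me3"}
    unknown = [m for m in marks if m not in known and not m.startswith("mark")]
    if unknown:
        raise ValueError(f"unknown marks: {unknown}")
    rng = np.random.default_rng(seed)
    by_id = {r.id: r for r in catalog}
    plan = _enrichment_plan(truth, marks, active_marks)
    reads_out: dict[str, ReadStartSet] = {}
    peaks_out: dict[str, list[GenomicInterval]] = {}

    for mark in marks:
        chroms: list[np.ndarray] = []
        positions: list[np.ndarray] = []
        strands: list[np.ndarray] = []
        peaks: list[GenomicInterval] = []
        for rid in sorted(plan[mark]):
            tmpl_name, scale = plan[mark][rid]
            r = by_id.get(rid)
            if r is None:
                continue
            n = int(rng.poisson(depth * scale))
            if n:
                weights = SHAPE_BY_NAME[tmpl_name].values
                per_bin = rng.multinomial(n, weights)
                bins = np.repeat(np.arange(N_BINS_RAW), per_bin)
                if r.strand == "-":
                    bins = N_BINS_RAW - 1 - bins  # orient template to genome
                pos = (
                    r.anchor
                    - FLANK_BP
                    + bins * BIN_BP
                    + rng.integers(0, BIN_BP, size=n)
                )
                strand = np.where(rng.random(n) < 0.5, "+", "-")
                # un-shift so that shift_read_starts(+100/-100) re-centers
                pos = np.where(strand == "+", pos - SHIFT_BP, pos + SHIFT_BP)
                pos = np.clip(pos, 0, chrom_sizes[r.chrom] - 1)
                chroms.append(np.full(n, r.chrom, dtype=object))
                positions.append(pos.astype(np.int64))
                strands.append(strand.astype(object))
            peaks.append(
                GenomicInterval(
                    r.chrom,
                    max(0, r.anchor - FLANK_BP),
                    min(chrom_sizes[r.chrom], r.anchor + FLANK_BP),
                    ".",
                )
            )
        # uniform background
        for chrom, size in chrom_sizes.items():
            n_bg = int(rng.poisson(noise_rate * size / 1000))
            if n_bg:
                chroms.append(np.full(n_bg, chrom, dtype=object))
                positions.append(rng.integers(0, size, n_bg, dtype=np.int64))
                strands.append(
                    np.where(rng.random(n_bg) < 0.5, "+", "-").astype(object)
                )
        if chroms:
            reads_out[mark] = ReadStartSet(
                mark,
                np.concatenate(chroms),
                np.concatenate(positions),
                np.concatenate(strands),
            )
        else:
            reads_out[mark] = ReadStartSet.from_records(mark, [])
        peaks_out[mark] = sorted(peaks, key=lambda p: (p.chrom, p.start))
    return reads_out, peaks_out


def generate_nucleosome_track(
    truth: PlantedTruth,
    catalog: list[RtssRecord],
    chrom_sizes: dict[str, int],
    depth: float = 100.0,
) -> SignalTrack:
    """Binned nucleosome occupancy: depleted center at expressed RTSSs
    (flanking +1/-1 nucleosomes), retained central nucleosome at poised
    ones."""
    per_chrom: dict[str, np.ndarray] = {
        c: np.zeros(size // BIN_BP) for c, size in chrom_sizes.items()
    }
    for r in catalog:
        row = truth.table.loc[r.id]
        if row["expression_class"] == rc.EXPRESSED:
            tmpl = SHAPE_BY_NAME["symmetric_dip"].values
        elif row["poised"]:
            tmpl = SHAPE_BY_NAME["center_peak"].values
        else:
            continue
        vals = tmpl * depth
        if r.strand == "-":
            vals = vals[::-1]
        start_bin = (r.anchor - FLANK_BP) // BIN_BP
        arr = per_chrom[r.chrom]
        for b, v in enumerate(vals):
            g = start_bin + b
            if 0 <= g < len(arr):
                arr[g] += v
    track = SignalTrack()
    for chrom, arr in per_chrom.items():
        nz = np.nonzero(arr)[0]
        if len(nz):
            starts = nz * BIN_BP
            track.add_chrom(chrom, starts, starts + BIN_BP, arr[nz] / BIN_BP)
    return track


def generate_cpg_islands(
    catalog: list[RtssRecord],
    truth: PlantedTruth,
    chrom_sizes: dict[str, int],
    seed: int | None = None,
    p_expressed: float = 0.7,
    p_other: float = 0.1,
    island_bp: int = 400,
) -> list[GenomicInterval]:
    """CpG islands covering promoters of (mostly expressed) RTSSs."""
    rng = np.random.default_rng(seed)
    islands = []
    for r in catalog:
        expressed = truth.table.loc[r.id, "expression_class"] == rc.EXPRESSED
        p = p_expressed if expressed else p_other
        if rng.random() < p:
            s = max(0, r.anchor - island_bp // 2)
            e = min(chrom_sizes[r.chrom], s + island_bp)
            if s < e:
                islands.append(GenomicInterval(r.chrom, s, e, "."))
    islands.sort(key=lambda p: (p.chrom, p.start))
    return islands


def generate_excludable_regions(
    chrom_sizes: dict[str, int],
    catalog: list[RtssRecord],
    seed: int | None = None,
    n_regions: int = 10,
    region_bp: int = 2000,
) -> list[GenomicInterval]:
    """A few unmappable-style regions placed clear of every RTSS, so the
    mappability filter is exercised without disturbing planted counts."""
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for r in catalog:
        occupied.setdefault(r.chrom, []).append(
            (r.interval.start - region_bp, r.interval.end + region_bp)
        )
    out: list[GenomicInterval] = []
    chroms = list(chrom_sizes)
    attempts = 0
    while len(out) < n_regions and attempts < 1000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, chrom_sizes[chrom] - region_bp))
        if any(s < e and o_s < s + region_bp for o_s, e in occupied.get(chrom, [])):
            continue
        out.append(GenomicInterval(chrom, s, s + region_bp, "."))
    out.sort(key=lambda p: (p.chrom, p.start))
    return out


# --------------------------------------------------------------- dataset

DEFAULT_MARKS = ("DNaseHS", "H2A.Z", "H3K4me3", "H3K27ac", "H3K9ac", "H3K79me2")


def generate_dataset(
    n_rtss: int = 2000,
    S: int = 100,
    n_chroms: int = 2,
    chrom_length: int = 10_000_000,
    n_genes: int = 600,
    marks: tuple[str, ...] = DEFAULT_MARKS,
    depth: float = 500.0,
    noise_rate: float = 0.2,
    threshold: int = rc.DEFAULT_TAG_THRESHOLD,
    poised_fraction: float = 0.10,
    n_archetypes: int = 10,
    seed: int | None = 0,
) -> SyntheticDataset:
    """One self-contained synthetic study at the default desk scale:
    2000 RTSSs, 6 active marks + Pol II, 100 pseudo-samples."""
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31, size=6)]
    genes, sizes = generate_genome(n_chroms, chrom_length, n_genes, sub[0])
    catalog, expr, truth = generate_rtss_set(
        genes,
        sizes,
        n_rtss,
        S,
        seed=sub[1],
        threshold=threshold,
        poised_fraction=poised_fraction,
        n_archetypes=n_archetypes,
        marks=list(marks),
    )
    all_marks = list(marks) + [POL2_MARK]
    reads, peaks = generate_chip_reads(
        truth,
        catalog,
        all_marks,
        sizes,
        depth=depth,
        noise_rate=noise_rate,
        seed=sub[2],
        active_marks=tuple(marks),
    )
    nucleosome = generate_nucleosome_track(truth, catalog, sizes)
    cpg = generate_cpg_islands(catalog, truth, sizes, seed=sub[3])
    excludable = generate_excludable_regions(sizes, catalog, seed=sub[4])
    return SyntheticDataset(
        catalog=catalog,
        expression=expr,
        truth=truth,
        genes=genes,
        chrom_sizes=sizes,
        reads=reads,
        peaks=peaks,
        nucleosome=nucleosome,
        cpg_islands=cpg,
        excludable=excludable,
        marks=all_marks,
    )
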