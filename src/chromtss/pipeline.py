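"""Pipeline orchestration: stages wired in dependency order over a single
typed config, with per-stage derived seeds and provenance headers so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    association_validation as av,
    genomic_io as gio,
    overlap_enrichment as oe,
    poised_selection as ps,
    profile_engine as pe,
    rtss_classify as rc,
    shape_clustering as sc,
    synthetic_data as sd,
)
from .types import ExpressionMatrix, RtssRecord

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "classify",
    "overlap",
    "profiles",
    "cluster",
    "metacluster",
    "poised",
    "validate",
)


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the study's published settings."""

    outdir: str = "chromtss_out"
    seed: int = 0
    # synthetic-data stage (None disables simulation; inputs must then exist)
    simulate: bool = True
    n_rtss: int = 2000
    n_samples: int = 100
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 600
    marks: tuple[str, ...] = sd.DEFAULT_MARKS
    depth: float = 500.0
    noise_rate: float = 0.2
    poised_fraction: float = 0.10
    n_archetypes: int = 10
    # classification
    focal_sample: str = "focal"
    expression_threshold: int = 5
    proximal_bp: int = 150
    isolation_gap: int = 2000
    # overlap testing
    extension_bp: int = 500
    n_perm_overlap: int = 100
    # profiles
    bin_bp: int = 100
    flank_bp: int = 3000
    shift_bp: int = 100
    min_reads: int = 100
    # clustering
    k_subprofiles: int = 5
    k_metaclusters: int = 10
    npass_level1: int = 200
    npass_level2: int = 1000
    # poised selection
    pooled_min_reads: float = 1000.0
    min_corr_repressed: float = 0.5
    max_p: float = 0.05
    per_mark_min_reads: float = 100.0
    min_marks_passing: int = 3
    # validation
    half_widths: tuple[int, ...] = av.DEFAULT_HALF_WIDTHS
    n_random_baseline: int = 100
    n_perm_cpg: int = 1000
    term_table: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("marks", "half_widths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        # where results land does not change what they are
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def derive_stage_seeds(master_seed: int, stage_name: str) -> int:
    """Deterministic, collision-resistant per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{stage_name}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# chromtss stage={stage} config={cfg.config_hash()} "
            f"seed={derive_stage_seeds(cfg.seed, stage)}\n"
        )
        df.to_csv(fh, sep="\t", **kw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_simulate(cfg: PipelineConfig, out: Path) -> sd.SyntheticDataset:
    ds = sd.generate_dataset(
        n_rtss=cfg.n_rtss,
        S=cfg.n_samples,
        n_chroms=cfg.n_chroms,
        chrom_length=cfg.chrom_length,
        n_genes=cfg.n_genes,
        marks=cfg.marks,
        depth=cfg.depth,
        noise_rate=cfg.noise_rate,
        threshold=cfg.expression_threshold,
        poised_fraction=cfg.poised_fraction,
        n_archetypes=cfg.n_archetypes,
        seed=derive_stage_seeds(cfg.seed, "simulate"),
    )
    gio.write_rtss_catalog(ds.catalog, out / "catalog.bed")
    gio.write_expression_matrix(ds.expression, out / "expression.tsv")
    gio.write_genes(ds.genes, out / "genes.tsv")
    gio.write_chrom_sizes(ds.chrom_sizes, out / "chrom.sizes")
    ds.truth.write_tsv(out / "truth.tsv")
    for mark in ds.marks:
        gio.write_tags(ds.reads[mark], out / f"tags_{mark}.bed")
        gio.write_peaks(ds.peaks[mark], out / f"peaks_{mark}.broadPeak")
    gio.write_signal_bedgraph(ds.nucleosome, out / "nucleosome.bedGraph")
    gio.write_peaks(ds.cpg_islands, out / "cpg_islands.bed")
    gio.write_peaks(ds.excludable, out / "excludable.bed")
    return ds


def _load_inputs(cfg: PipelineConfig, out: Path):
    catalog = gio.read_rtss_catalog(out / "catalog.bed")
    expr = gio.read_expression_matrix(out / "expression.tsv")
    genes = gio.read_genes(out / "genes.tsv")
    sizes = gio.read_chrom_sizes(out / "chrom.sizes")
    marks = list(cfg.marks) + [ps.POL2_MARK]
    reads, peaks = {}, {}
    for mark in marks:
        tags_path = out / f"tags_{mark}.bed"
        peaks_path = out / f"peaks_{mark}.broadPeak"
        if not tags_path.exists() or not peaks_path.exists():
            raise FileNotFoundError(f"missing input files for mark {mark}")
        reads[mark] = gio.read_tags(tags_path, mark)
        peaks[mark] = gio.read_peaks(peaks_path)
    excludable = (
        gio.read_bed_intervals(out / "excludable.bed")
        if (out / "excludable.bed").exists()
        else []
    )
    cpg = (
        gio.read_bed_intervals(out / "cpg_islands.bed")
        if (out / "cpg_islands.bed").exists()
        else []
    )
    return catalog, expr, genes, sizes, marks, reads, peaks, excludable, cpg


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage in dependency order; returns the results directory."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if cfg.simulate:
            _stage_simulate(cfg, out)
        (
            catalog,
            expr,
            genes,
            sizes,
            marks,
            reads,
            peaks,
            excludable,
            cpg,
        ) = _load_inputs(cfg, out)

        # ------------------------------------------------------- classify
        stage = "classify"
        catalog = rc.filter_unmappable(catalog, excludable)
        logger.info("classify: %d RTSSs after mappability filter", len(catalog))
        expression = rc.classify_expression(
            expr, cfg.focal_sample, cfg.expression_threshold
        )
        location = rc.classify_location(catalog, genes, cfg.proximal_bp)
        isolated = rc.find_isolated(catalog, cfg.isolation_gap)
        cls_table = rc.classification_table(catalog, expression, location, isolated)
        _write_tsv(cls_table, out / "classification.tsv", cfg, stage)
        for name, grp in cls_table.groupby(["expression_class", "location_class"]):
            logger.info("classify: %s -> %d", name, len(grp))

        expressed_ids = list(cls_table.index[cls_table.expression_class == rc.EXPRESSED])
        repressed_ids = list(cls_table.index[cls_table.expression_class == rc.REPRESSED])
        by_id = {r.id: r for r in catalog}

        # -------------------------------------------------------- overlap
        stage = "overlap"
        seed_ov = derive_stage_seeds(cfg.seed, stage)
        rows = []
        for i, mark in enumerate(marks):
            for cls_name, ids in (("expressed", expressed_ids), ("repressed", repressed_ids)):
                for iso_only in (False, True):
                    use = [
                        by_id[x]
                        for x in ids
                        if not iso_only or x in isolated
                    ]
                    if not use:
                        continue
                    st = oe.overlap_stats(
                        mark,
                        cls_name + ("_isolated" if iso_only else ""),
                        use,
                        peaks[mark],
                        sizes,
                        n_perm=cfg.n_perm_overlap,
                        seed=seed_ov + i,
                        extension=cfg.extension_bp,
                    )
                    rows.append(vars(st))
        _write_tsv(pd.DataFrame(rows), out / "overlap_stats.tsv", cfg, stage, index=False)

        # ------------------------------------------------------- profiles
        stage = "profiles"
        raw_profiles: dict[str, pd.DataFrame] = {}
        for mark in marks:
            raw = pe.profile_matrix(
                reads[mark], catalog, cfg.bin_bp, cfg.flank_bp, cfg.shift_bp
            )
            raw_profiles[mark] = raw
            _write_tsv(raw, out / f"profiles_{mark}.tsv", cfg, stage)

        # -------------------------------------------------------- cluster
        stage = "cluster"
        seed_cl = derive_stage_seeds(cfg.seed, stage)
        per_mark: dict[str, tuple[pd.DataFrame, pd.Series, sc.SubprofileSet]] = {}
        smoothed_by_mark: dict[str, pd.DataFrame] = {}
        for i, mark in enumerate(cfg.marks):
            raw = raw_profiles[mark].loc[
                raw_profiles[mark].index.intersection(expressed_ids)
            ]
            kept = pe.filter_low_signal(raw, cfg.min_reads)
            logger.info("cluster: %s -> %d/%d profiles kept", mark, len(kept), len(raw))
            if len(kept) < cfg.k_subprofiles:
                logger.warning("cluster: %s has too few profiles; skipped", mark)
                continue
            smoothed = pe.smooth_profiles(kept)
            subset = sc.kmeans_shapes(
                smoothed, mark, cfg.k_subprofiles, cfg.npass_level1, seed_cl + i
            )
            totals = raw.sum(axis=1)
            per_mark[mark] = (pe.smooth_profiles(raw), totals, subset)
            smoothed_by_mark[mark] = smoothed
            _write_tsv(
                pd.DataFrame(subset.subprofiles), out / f"subprofiles_{mark}.tsv", cfg, stage
            )
            _write_tsv(
                subset.assignments.rename("cluster").to_frame(),
                out / f"assignments_{mark}.tsv",
                cfg,
                stage,
                index_label="rtss_id",
            )

        # ---------------------------------------------------- metacluster
        stage = "metacluster"
        meta = sc.build_meta_matrix(
            per_mark, expressed_ids, mark_order=[m for m in cfg.marks if m in per_mark],
            min_signal=cfg.min_reads,
        )
        _write_tsv(meta, out / "meta_features.tsv", cfg, stage)
        result = sc.metacluster(
            meta,
            cfg.k_metaclusters,
            cfg.npass_level2,
            derive_stage_seeds(cfg.seed, stage),
        )
        _write_tsv(
            result.assignments.rename("metacluster").to_frame(),
            out / "metaclusters.tsv",
            cfg,
            stage,
            index_label="rtss_id",
        )
        heat = sc.metacluster_mark_averages(
            result, {m: per_mark[m][0] for m in per_mark}
        )
        _write_tsv(heat, out / "metacluster_profiles_long.tsv", cfg, stage, index=False)

        # --------------------------------------------------------- poised
        stage = "poised"
        criteria = ps.PoisedCriteria(
            pooled_min_reads=cfg.pooled_min_reads,
            min_corr_repressed=cfg.min_corr_repressed,
            max_p=cfg.max_p,
            per_mark_min_reads=cfg.per_mark_min_reads,
            min_marks_passing=cfg.min_marks_passing,
            extension_bp=cfg.extension_bp,
        )
        active = tuple(m for m in cfg.marks)
        active_raw = {m: raw_profiles[m] for m in active}
        all_ids = [r.id for r in catalog]
        pooled = ps.pool_active_profiles(active_raw, all_ids, active)
        has_peak = ps.peak_overlap_flags(
            catalog, {m: peaks[m] for m in active}, cfg.extension_bp
        )
        avg_rep, avg_exp = ps.reference_profiles(
            pooled, expressed_ids, repressed_ids, has_peak
        )
        pooled_res = ps.select_poised_pooled(
            repressed_ids, pooled, avg_rep, avg_exp, has_peak, criteria
        )
        _write_tsv(pooled_res.diagnostics, out / "poised_pooled.tsv", cfg, stage)
        per_mark_refs, per_mark_peaks = {}, {}
        for m in active:
            try:
                per_mark_refs[m] = ps.reference_profiles(
                    raw_profiles[m], expressed_ids, repressed_ids, has_peak
                )
            except ValueError:
                continue
            per_mark_peaks[m] = ps.peak_overlap_flags(
                catalog, {m: peaks[m]}, cfg.extension_bp
            )
        per_mark_res = ps.select_poised_per_mark(
            repressed_ids, active_raw, per_mark_refs, per_mark_peaks, criteria, active
        )
        _write_tsv(per_mark_res.diagnostics, out / "poised_per_mark.tsv", cfg, stage)
        comp = ps.compare_selections(set(pooled_res.selected), set(per_mark_res.selected))
        _write_tsv(
            pd.DataFrame([comp]), out / "poised_comparison.tsv", cfg, stage, index=False
        )
        logger.info(
            "poised: pooled=%d per-mark=%d", len(pooled_res.selected), len(per_mark_res.selected)
        )
        groups = {
            "expressed": expressed_ids,
            "poised": pooled_res.selected,
            "repressed": [x for x in repressed_ids if x not in set(pooled_res.selected)],
        }
        if all(groups.values()):
            rep = ps.profile_comparison_report(groups, raw_profiles[ps.POL2_MARK])
            _write_tsv(
                pd.DataFrame(rep).T, out / "group_profiles_PolII.tsv", cfg, stage,
                index_label="group",
            )

        # ------------------------------------------------------- validate
        stage = "validate"
        seed_val = derive_stage_seeds(cfg.seed, stage)
        reports = []
        for label, subset in (
            ("all", None),
            ("clusters", set(result.assignments.index)),
        ):
            for rep_item in av.window_intra_correlation(
                expr, catalog, genes, subset, cfg.half_widths, group=label
            ):
                reports.append(vars(rep_item))
        _write_tsv(pd.DataFrame(reports), out / "window_correlations.tsv", cfg, stage, index=False)
        baseline = av.random_baseline_correlation(
            expr, min(cfg.n_random_baseline, len(expr.rtss_ids)), seed_val
        )
        enr_rows = []
        background = av.promoter_regions(catalog, chrom_sizes=sizes)
        if cpg:
            for c in range(result.k):
                ids = set(result.assignments.index[result.assignments == c])
                members = [by_id[x] for x in ids if x in by_id]
                if not members:
                    continue
                proms = av.promoter_regions(members, chrom_sizes=sizes)
                enr = av.cpg_enrichment(proms, cpg, background, f"metacluster_{c}")
                enr_rows.append(vars(enr))
            if pooled_res.selected:
                proms = av.promoter_regions(
                    [by_id[x] for x in pooled_res.selected], chrom_sizes=sizes
                )
                enr = av.cpg_enrichment(proms, cpg, background, "poised")
                other = [
                    by_id[x]
                    for x in repressed_ids
                    if x not in set(pooled_res.selected)
                ]
                if other:
                    enr.p_value = av.cpg_case_control_test(
                        proms,
                        av.promoter_regions(other, chrom_sizes=sizes),
                        cpg,
                        cfg.n_perm_cpg,
                        seed_val,
                    )
                enr_rows.append(vars(enr))
        enr_df = pd.DataFrame(enr_rows)
        enr_df["random_baseline_r"] = baseline
        _write_tsv(enr_df, out / "cpg_enrichment.tsv", cfg, stage, index=False)
        if cfg.term_table:
            terms = pd.read_csv(cfg.term_table, sep="\t")
            mat = (
                terms.assign(v=1)
                .pivot_table(index="cluster", columns="gene", values="v", fill_value=0)
            )
            scores, evr = av.term_matrix_pca(mat)
            scores["explained_variance_1"] = evr[0]
            scores["explained_variance_2"] = evr[1]
            _write_tsv(scores, out / "term_pca.tsv", cfg, stage, index_label="cluster")
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise PipelineError(stage, exc) from exc
    return out
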