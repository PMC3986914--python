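import numpy as np
import pandas as pd
import pytest

from chromtss import association_validation as av
from chromtss.types import ExpressionMatrix, GenomicInterval, RtssRecord


def _rtss(rid, start, end, strand="+", chrom="chr1"):
    return RtssRecord(rid, GenomicInterval(chrom, start, end, strand))


def _tss_frame(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "tss": positions})


class TestWindowCorrelation:
    def test_identical_expression_gives_one(self):
        counts = pd.DataFrame(
            [[1, 5, 9, 2], [2, 10, 18, 4]], index=["a", "b"], dtype=float
        )
        expr = ExpressionMatrix(counts)
        catalog = [_rtss("a", 1000, 1100), _rtss("b", 1200, 1300)]
        reports = av.window_intra_correlation(
            expr, catalog, _tss_frame([1100]), half_widths=(500,), transform="raw"
        )
        assert reports[0].n_pairs == 1
        assert reports[0].mean_pairwise_r == pytest.approx(1.0)

    def test_empty_window_reports_no_mean(self):
        counts = pd.DataFrame([[1, 2, 3]], index=["a"], dtype=float)
        expr = ExpressionMatrix(counts)
        reports = av.window_intra_correlation(
            expr, [_rtss("a", 10_000, 10_100)], _tss_frame([100]), half_widths=(50,)
        )
        assert reports[0].n_pairs == 0 and reports[0].mean_pairwise_r is None

    def test_independent_expression_near_zero(self):
        rng = np.random.default_rng(1)
        n, S = 40, 200
        counts = pd.DataFrame(
            rng.poisson(20, (n, S)).astype(float), index=[f"r{i}" for i in range(n)]
        )
        expr = ExpressionMatrix(counts)
        catalog = [_rtss(f"r{i}", 1000 + 200 * i, 1100 + 200 * i) for i in range(n)]
        reports = av.window_intra_correlation(
            expr, catalog, _tss_frame([5000]), half_widths=(10_000,), transform="raw"
        )
        assert abs(reports[0].mean_pairwise_r) < 0.05

    def test_default_half_widths(self):
        assert av.DEFAULT_HALF_WIDTHS == (50, 200, 500, 1000, 5000, 10000, 50000, 150000)

    def test_subset_restriction(self):
        counts = pd.DataFrame(
            np.random.default_rng(2).poisson(10, (3, 10)).astype(float),
            index=["a", "b", "c"],
        )
        expr = ExpressionMatrix(counts)
        catalog = [_rtss("a", 1000, 1100), _rtss("b", 1200, 1300), _rtss("c", 1400, 1500)]
        reports = av.window_intra_correlation(
            expr, catalog, _tss_frame([1200]), rtss_subset={"a", "b"}, half_widths=(1000,)
        )
        assert reports[0].n_pairs == 1


class TestRandomBaseline:
    def test_two_sample_single_pair(self):
        counts = pd.DataFrame(
            [[1.0, 2, 3, 1], [2.0, 4, 6, 2]], index=["a", "b"]
        )
        expr = ExpressionMatrix(counts)
        r = av.random_baseline_correlation(expr, n_sample=2, seed=1, transform="raw")
        assert r == pytest.approx(1.0)

    def test_catalog_too_small_rejected(self):
        counts = pd.DataFrame([[1.0, 2]], index=["a"])
        with pytest.raises(ValueError):
            av.random_baseline_correlation(ExpressionMatrix(counts), n_sample=5)


class TestPromoters:
    def test_plus_strand_upstream(self):
        (p,) = av.promoter_regions([_rtss("a", 1000, 1100, "+")])
        assert (p.start, p.end) == (800, 1000)

    def test_minus_strand_downstream_coordinates(self):
        (p,) = av.promoter_regions([_rtss("a", 1000, 1100, "-")])
        assert (p.start, p.end) == (1100, 1300)

    def test_clipped_at_chromosome_start(self):
        (p,) = av.promoter_regions([_rtss("a", 50, 150, "+")])
        assert (p.start, p.end) == (0, 50)

    def test_clipped_at_chromosome_end(self):
        (p,) = av.promoter_regions(
            [_rtss("a", 900, 950, "-")], chrom_sizes={"chr1": 1000}
        )
        assert (p.start, p.end) == (950, 1000)


class TestCpGEnrichment:
    def _islands(self):
        return [GenomicInterval("chr1", 800, 1000)]

    def test_promoters_equal_background_ratio_one(self):
        proms = av.promoter_regions([_rtss("a", 1000, 1100), _rtss("b", 5000, 5100)])
        enr = av.cpg_enrichment(proms, self._islands(), proms)
        assert enr.ratio == pytest.approx(1.0)

    def test_fully_covered_vs_background_fraction(self):
        inside = av.promoter_regions([_rtss("a", 1000, 1100)])  # [800,1000) in island
        outside = av.promoter_regions([_rtss("b", 5000, 5100)])
        background = inside + outside
        enr = av.cpg_enrichment(inside, self._islands(), background)
        assert enr.ratio == pytest.approx(2.0)  # background fraction f=0.5 -> 1/f

    def test_no_overlap_ratio_zero(self):
        proms = av.promoter_regions([_rtss("b", 5000, 5100)])
        background = proms + av.promoter_regions([_rtss("a", 1000, 1100)])
        enr = av.cpg_enrichment(proms, self._islands(), background)
        assert enr.ratio == 0.0

    def test_union_ratio_between_parts(self):
        part1 = av.promoter_regions([_rtss("a", 1000, 1100)])
        part2 = av.promoter_regions([_rtss("b", 5000, 5100)])
        background = part1 + part2
        islands = self._islands()
        r1 = av.cpg_enrichment(part1, islands, background).ratio
        r2 = av.cpg_enrichment(part2, islands, background).ratio
        ru = av.cpg_enrichment(part1 + part2, islands, background).ratio
        assert min(r1, r2) <= ru <= max(r1, r2)

    def test_zero_expected_rejected(self):
        proms = av.promoter_regions([_rtss("b", 5000, 5100)])
        with pytest.raises(ValueError):
            av.cpg_enrichment(proms, [GenomicInterval("chr2", 0, 10)], proms)


class TestCpGCaseControl:
    def test_extreme_separation_hits_floor(self):
        case = [GenomicInterval("chr1", i * 1000, i * 1000 + 200) for i in range(20)]
        control = [
            GenomicInterval("chr1", 100_000 + i * 1000, 100_200 + i * 1000)
            for i in range(20)
        ]
        islands = [GenomicInterval("chr1", 0, 50_000)]
        p = av.cpg_case_control_test(case, control, islands, n_perm=199, seed=3)
        assert p == pytest.approx(1 / 200)

    def test_zero_permutations_rejected(self):
        iv = [GenomicInterval("chr1", 0, 100)]
        with pytest.raises(ValueError):
            av.cpg_case_control_test(iv, iv, iv, n_perm=0)

    def test_calibration_with_random_labels(self):
        rng = np.random.default_rng(4)
        proms = [
            GenomicInterval("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 500_000, 60)
        ]
        islands = [
            GenomicInterval("chr1", int(s), int(s) + 400)
            for s in np.sort(rng.choice(np.arange(0, 500_000, 1000), 80, replace=False))
        ]
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            perm = rng.permutation(len(proms))
            case = [proms[i] for i in perm[:30]]
            control = [proms[i] for i in perm[30:]]
            p = av.cpg_case_control_test(
                case, control, islands, n_perm=99, seed=int(rng.integers(2**31))
            )
            hits += p <= 0.05
        assert 0.01 <= hits / n_rep <= 0.12


class TestTermPca:
    def test_orthogonal_blocks_separate_on_pc1(self):
        m = pd.DataFrame(
            [[1, 1, 1, 0, 0, 0]] * 4 + [[0, 0, 0, 1, 1, 1]] * 4,
            index=[f"c{i}" for i in range(8)],
        )
        scores, evr = av.term_matrix_pca(m)
        pc1 = scores["PC1"].values
        assert (pc1[:4] > 0).all() != (pc1[4:] > 0).all()
        assert evr[0] > 0.9

    def test_identical_rows_zero_scores(self):
        m = pd.DataFrame([[1, 0, 1]] * 3)
        scores, evr = av.term_matrix_pca(m)
        assert np.allclose(scores.values, 0) and np.allclose(evr, 0)

    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.integers(0, 2, (4, 4)).astype(float))
        scores, evr = av.term_matrix_pca(m)
        x = m.values - m.values.mean(axis=0)
        cov = x.T @ x / 1.0
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        expected = x @ v[:, :2]
        for c in range(2):
            assert np.allclose(np.abs(scores.values[:, c]), np.abs(expected[:, c]), atol=1e-8)
        assert np.allclose(evr, w[:2] / w.sum())

    def test_row_order_invariance(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.integers(0, 2, (6, 5)).astype(float), index=list("abcdef"))
        s1, _ = av.term_matrix_pca(m)
        perm = list("fedcba")
        s2, _ = av.term_matrix_pca(m.loc[perm])
        assert np.allclose(s1.loc[perm].values, s2.values, atol=1e-10)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            av.term_matrix_pca(pd.DataFrame([[1.0]]))


def test_transform_rejects_unknown():
    with pytest.raises(ValueError):
        av.transform_expression(pd.DataFrame([[1.0]]), "sqrt")
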