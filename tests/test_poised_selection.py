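import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromtss import poised_selection as ps
from chromtss.profile_engine import smooth_profile


class TestDependentCorrTest:
    def test_equal_correlations_give_half(self):
        assert ps.dependent_corr_test(0.4, 0.4, 0.2, 48) == pytest.approx(0.5)

    def test_one_sided_swap_symmetry(self):
        p = ps.dependent_corr_test(0.7, 0.3, 0.1, 48)
        assert ps.dependent_corr_test(0.3, 0.7, 0.1, 48) == pytest.approx(1 - p)

    def test_strong_difference_significant(self):
        assert ps.dependent_corr_test(0.9, 0.1, 0.0, 48) < 0.001

    def test_monotone_decreasing_in_r_jk(self):
        ps_vals = [
            ps.dependent_corr_test(r, 0.2, 0.1, 48)
            for r in np.linspace(-0.5, 0.9, 20)
        ]
        assert all(a >= b for a, b in zip(ps_vals, ps_vals[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ps.dependent_corr_test(0.5, 0.5, 0.5, 3)
        with pytest.raises(ValueError):
            ps.dependent_corr_test(1.5, 0.5, 0.5, 48)

    def test_null_calibration_against_trivariate_normal(self):
        """Under a null where both correlations are truly equal, simulated
        p-values should be roughly uniform (size close to nominal)."""
        rng = np.random.default_rng(5)
        n, rho, r_kh = 48, 0.5, 0.3
        cov = np.array([[1, rho, rho], [rho, 1, r_kh], [rho, r_kh, 1]])
        L = np.linalg.cholesky(cov)
        pvals = []
        for _ in range(400):
            x = rng.standard_normal((n, 3)) @ L.T
            r = np.corrcoef(x.T)
            pvals.append(ps.dependent_corr_test(r[0, 1], r[0, 2], r[1, 2], n))
        frac = np.mean(np.array(pvals) <= 0.05)
        assert 0.01 <= frac <= 0.12


class TestPooling:
    def test_single_mark_identity(self):
        prof = pd.DataFrame(np.arange(60.0)[None, :], index=["a"])
        pooled = ps.pool_active_profiles({"H3K4me3": prof}, ["a"], ("H3K4me3",))
        assert np.array_equal(pooled.loc["a"].values, prof.loc["a"].values)

    def test_two_equal_marks_double(self):
        prof = pd.DataFrame(np.ones((1, 60)), index=["a"])
        pooled = ps.pool_active_profiles(
            {"H3K4me3": prof, "H3K27ac": prof.copy()}, ["a"], ("H3K4me3", "H3K27ac")
        )
        assert np.allclose(pooled.loc["a"].values, 2.0)

    def test_missing_id_contributes_zeros(self):
        prof = pd.DataFrame(np.ones((1, 60)), index=["a"])
        pooled = ps.pool_active_profiles({"H3K4me3": prof}, ["a", "b"], ("H3K4me3",))
        assert pooled.loc["b"].sum() == 0

    def test_default_active_panel_is_the_ten_activating_marks(self):
        assert set(ps.ACTIVE_MARKS) == {
            "DNaseHS", "H2A.Z", "H3K4me1", "H3K4me2", "H3K4me3",
            "H3K27ac", "H3K9ac", "H3K36me3", "H3K79me2", "H4K20me1",
        }


def _pooled_setup():
    """Three repressed candidates: one clear poised, one weak-total, one
    borderline-correlation."""
    rng = np.random.default_rng(6)
    peak = np.exp(-0.5 * ((np.arange(60) - 29.5) / 3) ** 2)
    dip = np.exp(-0.5 * ((np.arange(60) - 24) / 3) ** 2) + np.exp(
        -0.5 * ((np.arange(60) - 35) / 3) ** 2
    )
    avg_rep = smooth_profile(peak * 100)
    avg_exp = smooth_profile(dip * 100)
    rows = {
        "good": peak * 2000 / peak.sum(),   # total 2000, shape = repressed avg
        "weak": peak * 999 / peak.sum(),    # fails the 1000-read threshold
        "anti": dip * 2000 / dip.sum(),     # correlates with expressed avg
    }
    pooled = pd.DataFrame(np.vstack(list(rows.values())), index=list(rows))
    has_peak = pd.Series(True, index=list(rows))
    return pooled, avg_rep, avg_exp, has_peak


class TestPooledSelection:
    def test_conjunctive_criteria(self):
        pooled, avg_rep, avg_exp, has_peak = _pooled_setup()
        res = ps.select_poised_pooled(
            list(pooled.index), pooled, avg_rep, avg_exp, has_peak
        )
        assert res.selected == ["good"]
        d = res.diagnostics
        assert not d.loc["weak", "pass_total"]  # 999 is not above 1000
        assert not d.loc["anti", "pass_corr"] or not d.loc["anti", "pass_test"]

    def test_total_exactly_1000_rejected(self):
        pooled, avg_rep, avg_exp, has_peak = _pooled_setup()
        # integer read counts summing to exactly 1000
        counts = np.floor(pooled.loc["good"].values)
        counts[int(np.argmax(counts))] += 1000 - counts.sum()
        assert counts.sum() == 1000
        pooled.loc["good"] = counts
        res = ps.select_poised_pooled(
            list(pooled.index), pooled, avg_rep, avg_exp, has_peak
        )
        assert "good" not in res.selected  # strict "above 1000"

    def test_peak_overlap_required(self):
        pooled, avg_rep, avg_exp, has_peak = _pooled_setup()
        has_peak["good"] = False
        res = ps.select_poised_pooled(
            list(pooled.index), pooled, avg_rep, avg_exp, has_peak
        )
        assert res.selected == []

    def test_correlation_exactly_half_rejected(self):
        """'Above 0.5' is strict: r_repressed == 0.5 fails the criterion."""
        crit = ps.PoisedCriteria()
        df = ps._criteria_frame(
            ["at", "above"],
            totals=np.array([2000.0, 2000.0]),
            r_rep=np.array([0.5, 0.500001]),
            r_exp=np.array([0.0, 0.0]),
            pvals=np.array([0.01, 0.01]),
            has_peak=np.array([True, True]),
            criteria=crit,
        )
        assert not df.loc["at", "selected"]
        assert df.loc["above", "selected"]
        # p-value threshold is inclusive
        df2 = ps._criteria_frame(
            ["edge"],
            totals=np.array([2000.0]),
            r_rep=np.array([0.9]),
            r_exp=np.array([0.0]),
            pvals=np.array([0.05]),
            has_peak=np.array([True]),
            criteria=crit,
        )
        assert df2.loc["edge", "selected"]


class TestPerMarkSelection:
    def _build(self, n_good_marks):
        peak = np.exp(-0.5 * ((np.arange(60) - 29.5) / 3) ** 2)
        avg_rep = smooth_profile(peak * 10)
        avg_exp = smooth_profile(np.ones(60))
        marks = ["DNaseHS", "H2A.Z", "H3K4me3", "H3K27ac"]
        per_mark_raw, refs, has_peak = {}, {}, {}
        for i, m in enumerate(marks):
            strength = 500.0 if i < n_good_marks else 10.0
            prof = pd.DataFrame((peak * strength / peak.sum())[None, :], index=["x"])
            per_mark_raw[m] = prof
            refs[m] = (avg_rep, avg_exp)
            has_peak[m] = pd.Series({"x": True})
        return per_mark_raw, refs, has_peak

    def test_three_marks_passing_selected(self):
        raw, refs, hp = self._build(3)
        res = ps.select_poised_per_mark(["x"], raw, refs, hp)
        assert res.selected == ["x"]
        assert res.diagnostics.loc["x", "n_marks_passing"] == 3

    def test_two_marks_passing_rejected(self):
        raw, refs, hp = self._build(2)
        res = ps.select_poised_per_mark(["x"], raw, refs, hp)
        assert res.selected == []

    def test_zero_signal_rejected_everywhere(self):
        raw, refs, hp = self._build(0)
        res = ps.select_poised_per_mark(["x"], raw, refs, hp)
        assert res.diagnostics.loc["x", "n_marks_passing"] == 0


class TestComparisons:
    def test_identical_sets(self):
        out = ps.compare_selections({"a", "b"}, {"a", "b"})
        assert out == {"frac_of_a": 1.0, "frac_of_b": 1.0, "jaccard": 1.0}

    def test_disjoint_sets(self):
        out = ps.compare_selections({"a"}, {"b"})
        assert out["frac_of_a"] == out["frac_of_b"] == out["jaccard"] == 0.0

    def test_subset(self):
        out = ps.compare_selections(set("ab"), set("abcd"))
        assert out["frac_of_a"] == 1.0 and out["frac_of_b"] == 0.5


class TestGroupReport:
    def test_disjointness_enforced(self):
        prof = pd.DataFrame(np.ones((2, 60)), index=["a", "b"])
        with pytest.raises(ValueError, match="disjoint"):
            ps.profile_comparison_report({"g1": ["a"], "g2": ["a"]}, prof)

    def test_empty_group_rejected(self):
        prof = pd.DataFrame(np.ones((1, 60)), index=["a"])
        with pytest.raises(ValueError, match="empty"):
            ps.profile_comparison_report({"g1": ["a"], "g2": []}, prof)

    def test_single_member_group_is_own_profile(self):
        prof = pd.DataFrame(np.arange(120.0).reshape(2, 60), index=["a", "b"])
        out = ps.profile_comparison_report({"g1": ["a"], "g2": ["b"]}, prof)
        assert np.array_equal(out["g1"], prof.loc["a"].values)
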