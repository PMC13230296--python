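import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ctca_audit.pipeline import CaseRecord
from ctca_audit.stats import (cohort_analysis, pearson, stratify_calcium, welch_t)
import _oracles


class TestStratifyCalcium:
    @pytest.mark.parametrize("score,stratum", [
        (0, "none"), (0.5, "low"), (1, "low"), (50, "low"), (99, "low"),
        (100, "moderate"), (399, "moderate"), (400, "high"), (2500, "high"),
    ])
    def test_bins(self, score, stratum):
        assert stratify_calcium(score).value == stratum

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stratify_calcium(-1)


class TestPearson:
    def test_perfect_linearity(self):
        x = [1.0, 2.0, 5.0, 9.0]
        y = [2 * v + 1 for v in x]
        assert pearson(x, y).r == pytest.approx(1.0, abs=1e-12)

    def test_three_point_closed_form(self):
        res = pearson([1, 2, 3], [2, 1, 3])
        assert res.r == pytest.approx(0.5, abs=1e-10)
        assert res.n == 3

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1, 2, 3], [5, 5, 5])

    def test_matches_scipy_and_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = pearson(x, y)
            r_ref, p_ref = sps.pearsonr(x, y)
            assert res.r == pytest.approx(r_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)
            assert res.r == pytest.approx(_oracles.brute_pearson(list(x), list(y)), abs=1e-10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=20))
    def test_correlation_bounded(self, x):
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(x))
        xa = np.asarray(x)
        if np.var(xa) == 0 or np.var(y) == 0:
            return
        res = pearson(xa, y)
        assert -1.0 <= res.r <= 1.0
        assert 0.0 <= res.p <= 1.0


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        res = welch_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-10)
        assert res.t == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == pytest.approx(4.0, abs=1e-10)

    def test_equal_variance_equal_size_matches_pooled_t(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.5, 3.5, 4.5, 5.5]  # same variance, same n
        res = welch_t(a, b)
        t_pooled, _ = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(t_pooled, abs=1e-12)

    def test_matches_scipy_and_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.normal(size=int(rng.integers(2, 15)))
            b = rng.normal(2.0, 3.0, size=int(rng.integers(2, 15)))
            res = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)
            t_b, df_b = _oracles.brute_welch(list(a), list(b))
            assert res.t == pytest.approx(t_b, abs=1e-10)
            assert res.df == pytest.approx(df_b, abs=1e-10)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


def _record(i, sex, cohort, cac, dsc, cnr, ace, es, diam_lm, curv_lm, dsc_lm):
    from ctca_audit.stats import stratify_calcium

    return CaseRecord(
        id=f"r{i:02d}", sex=sex, cohort=cohort, calcium_score=cac,
        calcium_stratum=stratify_calcium(cac).value, tree_dsc=dsc, cnr=cnr,
        contrast_enhancement=ace, edge_sharpness=es,
        branch_dsc={"LM": dsc_lm}, branch_diameter={"LM": diam_lm},
        branch_curvature={"LM": curv_lm})


def hand_built_records():
    rows = [
        # i sex     cohort cac  dsc   cnr   ace  es  diam  curv  dsc_lm
        (0, "male", "A", 0, 0.90, 20.0, 300, 60, 4.0, 0.08, 0.91),
        (1, "male", "A", 0, 0.88, 18.0, 280, 55, 3.8, 0.09, 0.90),
        (2, "male", "A", 10, 0.86, 15.0, 260, 50, 3.6, 0.10, 0.87),
        (3, "female", "A", 0, 0.85, 14.0, 250, 48, 3.2, 0.11, 0.84),
        (4, "female", "A", 30, 0.83, 13.0, 240, 44, 3.1, 0.12, 0.83),
        (5, "female", "A", 120, 0.80, 12.0, 230, 40, 3.0, 0.13, 0.80),
        (6, "male", "B", 0, 0.82, 19.0, 290, 58, 3.9, 0.08, 0.85),
        (7, "male", "B", 5, 0.79, 16.0, 270, 52, 3.7, 0.09, 0.80),
        (8, "male", "B", 50, 0.77, 14.0, 250, 47, 3.5, 0.11, 0.78),
        (9, "female", "B", 0, 0.75, 13.0, 240, 45, 3.1, 0.12, 0.74),
        (10, "female", "B", 20, 0.73, 12.0, 235, 42, 3.0, 0.12, 0.72),
        (11, "female", "B", 200, 0.70, 11.0, 220, 38, 2.9, 0.14, 0.69),
    ]
    return [_record(*r) for r in rows]


class TestCohortAnalysis:
    def test_affine_dsc_gives_perfect_correlation(self):
        recs = hand_built_records()
        for r in recs:
            r.tree_dsc = 0.001 * r.contrast_enhancement + 0.5
        rep = cohort_analysis(recs)
        row = next(c for c in rep["quality_correlations"] if c["x"] == "contrast_enhancement")
        assert row["r"] == pytest.approx(1.0, abs=1e-9)

    def test_single_sex_rows_not_estimable(self):
        recs = [r for r in hand_built_records() if r.sex == "male"]
        rep = cohort_analysis(recs)
        female = [c for c in rep["branch_geometry_correlations"] if c["sex"] == "female"]
        assert female and all(not c["estimable"] for c in female)

    def test_hand_built_table_matches_independent_recomputation(self):
        recs = hand_built_records()
        rep = cohort_analysis(recs)

        # quality correlations vs scipy
        dsc = [r.tree_dsc for r in recs]
        for cell in rep["quality_correlations"]:
            x = [getattr(r, cell["x"]) for r in recs]
            r_ref, p_ref = sps.pearsonr(x, dsc)
            assert cell["r"] == pytest.approx(r_ref, abs=1e-10)
            assert cell["p"] == pytest.approx(p_ref, abs=1e-10)
            assert cell["n"] == 12

        # Welch per stratum vs scipy (cohort A vs B)
        for cell in rep["calcium_welch"]:
            ga = [r.tree_dsc for r in recs if r.cohort == "A" and r.calcium_stratum == cell["stratum"]]
            gb = [r.tree_dsc for r in recs if r.cohort == "B" and r.calcium_stratum == cell["stratum"]]
            if len(ga) >= 3 and len(gb) >= 3:
                ref = sps.ttest_ind(ga, gb, equal_var=False)
                assert cell["t"] == pytest.approx(ref.statistic, abs=1e-10)
                assert cell["p"] == pytest.approx(ref.pvalue, abs=1e-10)
            else:
                assert not cell["estimable"]

        # sex-stratified branch geometry vs scipy
        for cell in rep["branch_geometry_correlations"]:
            sel = [r for r in recs if r.sex == cell["sex"]]
            y = [r.branch_dsc["LM"] for r in sel]
            attr = "branch_diameter" if cell["x"] == "mean_diameter" else "branch_curvature"
            x = [getattr(r, attr)["LM"] for r in sel]
            r_ref, p_ref = sps.pearsonr(x, y)
            assert cell["r"] == pytest.approx(r_ref, abs=1e-10)
            assert cell["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_order_invariance(self):
        recs = hand_built_records()
        rep1 = cohort_analysis(recs)
        rep2 = cohort_analysis(list(reversed(recs)))
        assert rep1 == rep2

    def test_no_multiplicity_correction(self):
        # reported p's equal raw pairwise p's (nothing adjusted)
        recs = hand_built_records()
        rep = cohort_analysis(recs)
        dsc = [r.tree_dsc for r in recs]
        for cell in rep["quality_correlations"]:
            x = [getattr(r, cell["x"]) for r in recs]
            assert cell["p"] == pytest.approx(sps.pearsonr(x, dsc)[1], abs=1e-12)
        assert rep["multiplicity_correction"] == "none"

    def test_small_stratum_reported_not_raised(self):
        recs = hand_built_records()[:6]  # cohort A only
        rep = cohort_analysis(recs)
        assert all(not c["estimable"] for c in rep["calcium_welch"])
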