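import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from _oracles import enumerate_signed_rank_p
from cnvdosage.core import ExpressionMatrix
from cnvdosage.stats import (
    animal_effect_control,
    build_contrast,
    coverage_expression_correlation,
    lilliefors_test,
    signed_rank_W,
    spearman_RS,
    spearman_test,
    wilcoxon_test,
)
from cnvdosage.stats import test_contrast as run_contrast_test


class TestSignedRankW:
    @pytest.mark.parametrize(
        "diffs,expected",
        [
            ((1.0, 2.0, 3.0), 6.0),  # all positive: W = n(n+1)/2
            ((-1.0, -2.0, -0.5, -4.0), 0.0),  # no positive ranks
            ((3.0, -1.0, 2.0), 5.0),  # signed sum 4 -> W = 2 + 3
        ],
    )
    def test_hand_computed_cases(self, diffs, expected):
        w, n = signed_rank_W(diffs)
        assert w == expected
        assert n == len(diffs)

    def test_zero_differences_dropped(self):
        w, n = signed_rank_W([0.0, 1.0, 0.0, 2.0])
        assert (w, n) == (3.0, 2)
        assert signed_rank_W([0.0, 0.0]) == (0.0, 0)

    @given(
        st.lists(
            st.integers(min_value=-10_000, max_value=10_000).filter(lambda v: v != 0),
            min_size=1,
            max_size=40,
            unique_by=abs,
        )
    )
    def test_formula_equals_sum_of_positive_ranks(self, diffs):
        """The half-signed-rank-sum form is algebraically the positive-rank sum."""
        d = np.array(diffs, dtype=float)
        w, _ = signed_rank_W(d)
        ranks = sps.rankdata(np.abs(d))
        assert w == pytest.approx(ranks[d > 0].sum())


class TestWilcoxonTest:
    def test_identical_vectors_degenerate(self):
        res = wilcoxon_test([1.0, 2.0], [1.0, 2.0])
        assert (res.p_value, res.n, res.method) == (1.0, 0, "degenerate")

    def test_exact_one_sided_three_positives(self):
        res = wilcoxon_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], alternative="greater")
        assert res.p_value == pytest.approx(1 / 8)
        assert res.method == "exact"

    def test_exact_matches_full_enumeration(self):
        rng = np.random.default_rng(2)
        for n in range(2, 11):
            x = np.zeros(n)
            y = rng.normal(size=n)
            for alt in ("two_sided", "greater", "less"):
                res = wilcoxon_test(x, y, alt)
                assert res.p_value == pytest.approx(
                    enumerate_signed_rank_p(y, alt), abs=1e-12
                )

    def test_exact_agrees_with_scipy_one_sided(self):
        rng = np.random.default_rng(9)
        d = rng.normal(size=15)
        ours = wilcoxon_test(np.zeros(15), d, "greater")
        ref = sps.wilcoxon(d, alternative="greater", mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact_at_n20(self):
        rng = np.random.default_rng(4)
        from cnvdosage.stats import _normal_approx_p

        for _ in range(10):
            d = rng.normal(0.2, 1.0, size=20)
            for alt in ("greater", "less"):
                exact = wilcoxon_test(np.zeros(20), d, alt)
                assert exact.method == "exact"
                approx = _normal_approx_p(exact.statistic, 20, np.ones(20), alt)
                assert abs(approx - exact.p_value) < 0.005

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            wilcoxon_test([1.0], [1.0, 2.0])


class TestLilliefors:
    def test_normal_sample_not_rejected(self):
        x = sps.norm.ppf((np.arange(1, 101) - 0.5) / 100)  # perfect agreement
        res = lilliefors_test(x, n_sims=2000, rng=0)
        assert res.p_value > 0.5

    def test_lognormal_sample_rejected_across_seeds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.lognormal(0, 1, size=200)
            res = lilliefors_test(x, n_sims=2000, rng=1)
            assert res.p_value < 0.05

    def test_statistic_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        d_sm, _ = sm_lilliefors(x, dist="norm")
        res = lilliefors_test(x, n_sims=500, rng=0)
        assert res.statistic == pytest.approx(d_sm, abs=1e-12)

    def test_duplicate_heavy_sample_handled(self):
        x = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0])
        res = lilliefors_test(x, n_sims=500, rng=0)
        assert 0 <= res.p_value <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            lilliefors_test([2.0, 2.0, 2.0, 2.0])


class TestSpearman:
    def test_perfect_concordance_and_reversal(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = spearman_test(a, a)
        assert res.statistic == 1.0
        assert res.method == "enumeration_limit"
        assert res.p_value == pytest.approx(2 / 24)
        rev = spearman_test(a, a[::-1])
        assert rev.statistic == -1.0

    def test_hand_computed_rank_difference_case(self):
        # ranks (1,2,3,4) vs (2,1,4,3): sum d^2 = 4, R_S = 1 - 24/60
        assert spearman_RS([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_matches_scipy_tie_free(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(2, 30))
        ours = spearman_test(a, b)
        ref = sps.spearmanr(a, b)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_ties_use_rank_product_moment(self):
        a = [1.0, 1.0, 2.0, 3.0, 4.0, 4.0]
        b = [2.0, 1.0, 3.0, 5.0, 4.0, 6.0]
        ours = spearman_test(a, b)
        ref = sps.spearmanr(a, b)
        assert ours.statistic == pytest.approx(ref.statistic)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_formula_equals_rank_correlation(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 12))
        rs = spearman_RS(sps.rankdata(a), sps.rankdata(b))
        assert rs == pytest.approx(np.corrcoef(sps.rankdata(a), sps.rankdata(b))[0, 1])

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            spearman_test([1.0, 2.0], [2.0, 1.0])


def _expr(values: dict, samples) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values, index=samples).T)


def _overlap_row(tid, animal, region_class="coding", cnv_type="deletion"):
    return {
        "animal_id": animal,
        "cnv_type": cnv_type,
        "chrom": "1",
        "cnv_start": 0,
        "cnv_end": 100,
        "transcript_id": tid,
        "region_class": region_class,
        "overlap_bp": 100,
        "percent_covered": 0.1,
    }


SAMPLES = [f"animal{i}" for i in range(1, 7)]


class TestBuildContrast:
    def test_single_carrier_means(self):
        expr = _expr({"t1": [2.0, 4.0, 4.0, 4.0, 4.0, 4.0]}, SAMPLES)
        table = pd.DataFrame([_overlap_row("t1", "animal1")])
        c = build_contrast(expr, table, "coding", "deletion")
        assert c.n == 1
        assert (c.x_carrier[0], c.y_noncarrier[0]) == (2.0, 4.0)

    def test_six_of_six_carriers_excluded(self):
        expr = _expr({"t1": [1.0] * 6}, SAMPLES)
        table = pd.DataFrame([_overlap_row("t1", a) for a in SAMPLES])
        assert build_contrast(expr, table, "coding", "deletion").n == 0

    def test_updown_pools_both_flanks(self):
        expr = _expr({"t1": [1, 2, 3, 4, 5, 6], "t2": [6, 5, 4, 3, 2, 1]}, SAMPLES)
        table = pd.DataFrame(
            [
                _overlap_row("t1", "animal1", region_class="upstream"),
                _overlap_row("t2", "animal2", region_class="downstream"),
            ]
        )
        assert build_contrast(expr, table, "updown", "deletion").n == 2

    def test_empty_contrast_refused_by_test(self):
        expr = _expr({"t1": [1.0] * 6}, SAMPLES)
        table = pd.DataFrame(columns=list(_overlap_row("x", "a")))
        out = run_contrast_test(build_contrast(expr, table, "coding", "deletion"))
        assert out["n"] == 0 and out["p_value"] is None
        assert "refused" in out["message"]


class TestAnimalEffectControl:
    def _null_expr(self, rng, n=300):
        vals = rng.lognormal(3, 0.5, size=(n, 6))
        return ExpressionMatrix(
            pd.DataFrame(vals, index=[f"t{i}" for i in range(n)], columns=SAMPLES)
        )

    def test_single_rep_returns_one_p(self):
        rng = np.random.default_rng(0)
        out = animal_effect_control(
            self._null_expr(rng), pd.DataFrame({"transcript_id": []}), n_reps=1, rng=0
        )
        assert len(out["p_values"]) == 1

    def test_global_animal_effect_detected(self):
        rng = np.random.default_rng(1)
        expr = self._null_expr(rng)
        doubled = expr.tpm.copy()
        doubled["animal1"] *= 2.0
        out = animal_effect_control(
            ExpressionMatrix(doubled), pd.DataFrame({"transcript_id": []}),
            n_reps=100, rng=0,
        )
        assert out["fraction_significant"] > 0.5

    def test_no_effect_near_alpha(self):
        rng = np.random.default_rng(2)
        out = animal_effect_control(
            self._null_expr(rng), pd.DataFrame({"transcript_id": []}),
            n_reps=200, rng=0,
        )
        assert abs(out["fraction_significant"] - 0.05) < 0.05

    def test_empty_pool_rejected(self):
        rng = np.random.default_rng(0)
        expr = self._null_expr(rng, n=5)
        table = pd.DataFrame({"transcript_id": [f"t{i}" for i in range(5)]})
        with pytest.raises(ValueError, match="pool|CNV-free"):
            animal_effect_control(expr, table, n_reps=1, rng=0)


class TestCoverageCorrelation:
    def test_constant_percent_not_computable(self):
        expr = _expr(
            {f"t{i}": list(np.arange(6, dtype=float) + i) for i in range(5)}, SAMPLES
        )
        rows = [
            dict(_overlap_row(f"t{i}", "animal1"), percent_covered=0.5) for i in range(5)
        ]
        out = coverage_expression_correlation(expr, pd.DataFrame(rows))
        cell = out[
            (out.animal_id == "animal1")
            & (out.cnv_type == "deletion")
            & (out.region_class == "coding")
        ].iloc[0]
        assert cell["n"] == 5 and np.isnan(cell["r_s"])

    def test_strong_negative_dependence_recovered(self):
        rng = np.random.default_rng(6)
        n = 30
        pct = rng.uniform(0.05, 0.95, size=n)
        tids = [f"t{i}" for i in range(n)]
        vals = {}
        for tid, p in zip(tids, pct):
            base = 100.0
            row = [base * (1 - 0.8 * p)] + [base] * 5  # carrier animal1 reduced by coverage
            vals[tid] = row
        expr = _expr(vals, SAMPLES)
        rows = [
            dict(_overlap_row(tid, "animal1"), percent_covered=p)
            for tid, p in zip(tids, pct)
        ]
        out = coverage_expression_correlation(expr, pd.DataFrame(rows))
        cell = out[
            (out.animal_id == "animal1")
            & (out.cnv_type == "deletion")
            & (out.region_class == "coding")
        ].iloc[0]
        assert cell["r_s"] < -0.9 and cell["p_value"] < 1e-6
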