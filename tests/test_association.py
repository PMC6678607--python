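import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tnbc_immune import association as assoc
from tnbc_immune.cohort_io import CBCRecord, ValidationError

from .oracles import kruskal_h_bruteforce, logistic_ml_or_2x2


class TestRatios:
    def test_plr_and_nlr_division(self):
        records = [CBCRecord("S1", neutrophils=4.40, lymphocytes=2.00,
                             platelets=252.0)]
        m = assoc.compute_ratios(records)
        assert m.plr.iloc[0] == pytest.approx(126.0)
        assert m.nlr.iloc[0] == pytest.approx(2.20)

    def test_zero_lymphocytes_error(self):
        df = pd.DataFrame({"neutrophils": [4.0], "lymphocytes": [0.0],
                           "platelets": [200.0]}, index=["S1"])
        with pytest.raises(ValidationError, match="lymphocyte"):
            assoc.compute_ratios(df)


class TestOddsRatio2x2:
    @pytest.mark.parametrize(
        "cells,or_str,ci_str",
        [
            ((16, 11, 11, 16), "2.12", "(0.71-6.27)"),
            ((18, 9, 9, 18), "4.00", "(1.29-12.40)"),
            ((14, 14, 13, 13), "1.00", "(0.34-2.91)"),
            ((10, 17, 17, 10), "0.35", "(0.11-1.04)"),
        ],
    )
    def test_reconstructed_study_tables(self, cells, or_str, ci_str):
        """2x2 cells rebuilt from the published group sizes and percentages
        reproduce the published OR and Wald CI strings at 2 dp."""
        res = assoc.odds_ratio_2x2(assoc.ContingencyTable2x2(*cells))
        assert f"{res.estimate:.2f}" == or_str
        assert f"({res.ci_low:.2f}-{res.ci_high:.2f})" == ci_str

    def test_symmetric_table_is_unity(self):
        for k in (1, 5, 13):
            res = assoc.odds_ratio_2x2(assoc.ContingencyTable2x2(k, k, k, k))
            assert res.estimate == pytest.approx(1.0)
            assert res.ci_low <= 1.0 <= res.ci_high

    def test_zero_cell_flagged_and_haldane_optional(self):
        t = assoc.ContingencyTable2x2(0, 5, 5, 5)
        assert t.has_zero_cell
        with pytest.raises(ValidationError, match="zero cell"):
            assoc.odds_ratio_2x2(t)
        res = assoc.odds_ratio_2x2(t, haldane=True)
        assert res.estimate == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))

    def test_matches_exhaustive_likelihood_logistic(self):
        """Crude 2x2 OR equals the OR from a direct numerical ML logistic fit
        (saturated-model equivalence), on random small tables."""
        rng = np.random.default_rng(21)
        for _ in range(8):
            cells = tuple(int(c) for c in rng.integers(1, 31, size=4))
            ours = assoc.odds_ratio_2x2(assoc.ContingencyTable2x2(*cells)).estimate
            oracle = logistic_ml_or_2x2(*cells)
            assert ours == pytest.approx(oracle, rel=1e-4)


class TestBinomialLogistic:
    def test_single_binary_covariate_equals_2x2(self):
        a, b, c, d = 16, 11, 11, 16
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        res = assoc.binomial_logistic(pd.DataFrame({"x": x}), y)[0]
        ref = assoc.odds_ratio_2x2(assoc.ContingencyTable2x2(a, b, c, d))
        assert res.estimate == pytest.approx(ref.estimate, rel=1e-6)
        assert res.ci_low == pytest.approx(ref.ci_low, rel=1e-6)
        assert res.ci_high == pytest.approx(ref.ci_high, rel=1e-6)

    def test_null_large_sample_or_near_one(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=2000)
        y = rng.integers(0, 2, size=2000)
        res = assoc.binomial_logistic(pd.DataFrame({"x": x}), y)[0]
        assert 0.9 < res.estimate < 1.1

    def test_constant_outcome_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValidationError, match="constant"):
            assoc.binomial_logistic(pd.DataFrame({"x": x}), np.ones(10))

    def test_perfect_separation_names_covariate(self):
        x = np.arange(20.0)
        y = (x >= 10).astype(float)
        with pytest.raises(ValidationError, match="separation.*'x'"):
            assoc.binomial_logistic(pd.DataFrame({"x": x}), y)


class TestMultinomialLogistic:
    @staticmethod
    def _labels(rng, n):
        return rng.choice(["ImA", "ImB", "ImC"], size=n)

    def test_null_ors_near_one(self):
        rng = np.random.default_rng(23)
        x = rng.normal(100, 20, size=3000)
        out = assoc.multinomial_logistic(x, self._labels(rng, 3000), unit_scale=10.0)
        for res in out.values():
            assert 0.9 < res.estimate < 1.1

    def test_location_invariance(self):
        rng = np.random.default_rng(24)
        x = rng.normal(150, 30, size=300)
        labels = self._labels(rng, 300)
        a = assoc.multinomial_logistic(x, labels, unit_scale=10.0)
        b = assoc.multinomial_logistic(x + 37.0, labels, unit_scale=10.0)
        for cls in a:
            assert a[cls].estimate == pytest.approx(b[cls].estimate, rel=1e-5)

    def test_reduces_to_pairwise_binomial(self):
        rng = np.random.default_rng(25)
        x = rng.normal(size=400)
        labels = self._labels(rng, 400)
        mn = assoc.multinomial_logistic(x, labels)
        mask = labels != "ImC"
        res = assoc.binomial_logistic(
            pd.DataFrame({"x": x[mask]}), (labels[mask] == "ImB").astype(float)
        )[0]
        # multinomial slope for ImB vs ImA approximates the pairwise binomial
        assert np.log(mn["ImB"].estimate) == pytest.approx(
            np.log(res.estimate), abs=0.15
        )

    def test_missing_reference_class_rejected(self):
        with pytest.raises(ValidationError, match="ImA"):
            assoc.multinomial_logistic(
                np.arange(12.0), ["ImB", "ImC"] * 6, ref="ImA"
            )


class TestRankStatistics:
    def test_spearman_monotone(self):
        rho, _ = assoc.spearman([1, 2, 3, 4], [10, 20, 25, 90])
        assert rho == pytest.approx(1.0)

    def test_kruskal_identical_groups_zero(self):
        h, p = assoc.kruskal_wallis([1.0, 2.0], [1.0, 2.0], [1.0, 2.0])
        assert h == 0.0 and p == 1.0

    def test_kruskal_matches_hand_formula(self):
        groups = ([1.0, 2.0], [3.0, 4.0], [5.0, 6.0])
        h, _ = assoc.kruskal_wallis(*groups)
        assert h == pytest.approx(kruskal_h_bruteforce(groups))
        assert h == pytest.approx(12 / (6 * 7) * (2 * 4 + 0 + 2 * 4))

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            assoc.kruskal_wallis([1.0], [])


class TestFisherKx2:
    def test_matches_scipy_on_2x2(self):
        rng = np.random.default_rng(26)
        for _ in range(10):
            t = rng.integers(0, 12, size=(2, 2)) + 1
            ours = assoc.fisher_exact_kx2(t)
            ref = stats.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_3x2_balanced_near_one(self):
        p = assoc.fisher_exact_kx2([[5, 5], [5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_3x2_extreme_association_small_p(self):
        p = assoc.fisher_exact_kx2([[10, 0], [0, 10], [5, 5]])
        assert p < 1e-3

    def test_zero_row_rejected(self):
        with pytest.raises(ValidationError):
            assoc.fisher_exact_kx2([[0, 0], [3, 4]])


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        fitters, _ = assoc.km_dfs([100, 400, 900], [0, 0, 0])
        assert (fitters["all"].survival_function_["all"] == 1.0).all()

    def test_identical_groups_logrank_near_one(self):
        times = [100, 300, 500, 700] * 2
        events = [1, 0, 1, 0] * 2
        groups = ["a"] * 4 + ["b"] * 4
        _, p = assoc.km_dfs(times, events, groups)
        assert p > 0.95

    def test_exponential_arms_recover_hazard_ratio(self):
        rng = np.random.default_rng(27)
        n = 500
        lam = 1 / 1000.0
        t1 = rng.exponential(1 / lam, size=n)
        t3 = rng.exponential(1 / (3 * lam), size=n)
        fitters, p = assoc.km_dfs(
            np.r_[t1, t3], np.ones(2 * n), ["slow"] * n + ["fast"] * n,
            horizon_days=1e9,
        )
        ratio = (fitters["slow"].median_survival_time_
                 / fitters["fast"].median_survival_time_)
        assert ratio == pytest.approx(3.0, rel=0.25)
        assert p < 1e-10

    def test_negative_times_rejected(self):
        with pytest.raises(ValidationError):
            assoc.km_dfs([-1.0], [1])


class TestQuadrants:
    def test_examples_and_boundary(self):
        out = assoc.quadrant_classify(
            x=[1.0, 1.0, -1.0, -1.0, 0.0], y=[1.0, -1.0, 1.0, -1.0, 0.0],
            x_cut=0.0, y_cut=0.0,
        )
        assert out.tolist() == ["Q2", "Q4", "Q1", "Q3", "Q3"]

    def test_nonfinite_cut_rejected(self):
        with pytest.raises(ValidationError):
            assoc.quadrant_classify([1.0], [1.0], np.nan, 0.0)

    def test_inflamed_cluster_concentrates_high_ims_quadrants(
        self, default_cohort, default_panel
    ):
        from tnbc_immune.cohort_io import clinical_to_frame

        clin = clinical_to_frame(default_cohort.clinical)
        ims = default_panel["ims"]
        t = clin["time_to_event_days"]
        out = assoc.quadrant_classify(ims, t, ims.mean(), t.mean())
        ima = out[default_cohort.truth_labels == "ImA"]
        assert (ima.isin(["Q2", "Q4"])).mean() > 0.8
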