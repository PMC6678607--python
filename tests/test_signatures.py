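import numpy as np
import pandas as pd
import pytest

from tnbc_immune.cohort_io import ExpressionMatrix, ValidationError
from tnbc_immune.signatures import (
    SignatureConfig,
    aggressive_score,
    cyt_score,
    dichotomize_by_median,
    estimate_scores,
    immunophenoscore,
    ims_score,
    purity_from_estimate,
    ssgsea,
    tils_high_flag,
    tis_score,
)

from .conftest import random_expression


def expr_from(rows: dict, samples=None) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"S{j}" for j in range(df.shape[1])]
    return ExpressionMatrix(df)


class TestCYT:
    def test_mean_of_log2_values(self):
        expr = expr_from({"GZMA": [8.0, 4.0], "PRF1": [6.0, 4.0]})
        out = cyt_score(expr)
        assert out.tolist() == [7.0, 4.0]

    def test_equal_inputs_idempotent(self):
        expr = expr_from({"GZMA": [5.5, 6.25], "PRF1": [5.5, 6.25]})
        assert cyt_score(expr).tolist() == [5.5, 6.25]

    def test_linear_scale_is_log2_geometric_mean(self):
        df = pd.DataFrame({"S1": [4.0, 9.0], "S2": [2.0, 8.0]},
                          index=["GZMA", "PRF1"])
        expr = ExpressionMatrix(df, scale_tag="linear")
        out = cyt_score(expr)
        np.testing.assert_allclose(out["S1"], np.log2(6.0), atol=1e-12)  # gm(4,9)=6
        np.testing.assert_allclose(out["S1"], 2.585, atol=1e-3)

    def test_missing_gene_named_in_error(self):
        expr = expr_from({"GZMA": [1.0, 2.0], "CD8A": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="PRF1"):
            cyt_score(expr)


class TestTIS:
    def test_constant_panel(self):
        cfg = SignatureConfig()
        expr = expr_from({g: [8.26, 8.26] for g in cfg.tis_gene_list})
        np.testing.assert_allclose(tis_score(expr, cfg), 8.26)

    def test_half_six_half_eight(self):
        cfg = SignatureConfig()
        genes = cfg.tis_gene_list
        rows = {g: [6.0, 6.0] for g in genes[:9]}
        rows.update({g: [8.0, 8.0] for g in genes[9:]})
        expr = expr_from(rows)
        np.testing.assert_allclose(tis_score(expr, cfg), 7.0)

    def test_absent_genes_warn_and_zero_genes_error(self):
        cfg = SignatureConfig()
        present = cfg.tis_gene_list[:3]
        expr = expr_from({g: [6.0, 6.0] for g in present})
        with pytest.warns(UserWarning, match="absent"):
            out = tis_score(expr, cfg)
        assert (out == 6.0).all()
        none = expr_from({"X1": [1.0, 2.0], "X2": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="no TIS genes"):
            tis_score(none, cfg)


class TestAggressive:
    def test_coefficient_sum_on_unit_input(self):
        expr = expr_from({"CCL5": [1.0, 1.0], "DDIT4": [1.0, 1.0],
                          "POLR1C": [1.0, 1.0]})
        np.testing.assert_allclose(aggressive_score(expr), 0.540, atol=1e-12)

    def test_single_gene_contribution(self):
        expr = expr_from({"CCL5": [10.0, 10.0], "DDIT4": [0.0, 0.0],
                          "POLR1C": [0.0, 0.0]})
        np.testing.assert_allclose(aggressive_score(expr), -3.93, atol=1e-12)

    def test_missing_gene_is_error(self):
        expr = expr_from({"CCL5": [1.0, 1.0], "DDIT4": [1.0, 1.0]})
        with pytest.raises(ValidationError, match="POLR1C"):
            aggressive_score(expr)


class TestIMS:
    def test_study_median_profile(self):
        # 7.11 * 8.26 - 2.85 = 55.8786 -> 55.88 at 2 dp
        out = ims_score([7.11], [8.26], [2.85])
        assert round(float(out.iloc[0]), 2) == 55.88

    def test_zero_cyt_gives_minus_aggressive(self):
        out = ims_score([0.0, 0.0], [3.0, 9.9], [1.5, -2.0])
        assert out.tolist() == [-1.5, 2.0]

    def test_unit_profile(self):
        assert float(ims_score([1.0], [1.0], [0.0]).iloc[0]) == 1.0

    def test_exactness_on_random_panels(self):
        rng = np.random.default_rng(42)
        cyt, tis, aggr = rng.normal(size=(3, 200))
        out = ims_score(cyt, tis, aggr)
        np.testing.assert_array_equal(out.to_numpy(), cyt * tis - aggr)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            ims_score([1.0, 2.0], [1.0], [0.0])


class TestSSGSEAProperties:
    def test_top_k_set_is_extremal(self):
        rng = np.random.default_rng(3)
        expr = random_expression(rng, 12, 2)
        x = expr.values["S0"]
        k = 4
        top = set(x.sort_values(ascending=False).index[:k])
        top_score = ssgsea(expr, {"top": sorted(top)}, min_size=2,
                           normalize=False).loc["S0", "top"]
        for _ in range(30):
            other = set(rng.choice(expr.gene_ids, size=k, replace=False))
            s = ssgsea(expr, {"o": sorted(other)}, min_size=2,
                       normalize=False).loc["S0", "o"]
            assert s <= top_score + 1e-9

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(4)
        expr = random_expression(rng, 30, 5, ties=True)
        perm = rng.permutation(30)
        shuffled = ExpressionMatrix(expr.values.iloc[perm])
        sets = {"A": [f"G{i}" for i in range(0, 12)]}
        a = ssgsea(expr, sets, min_size=5, normalize=False)
        b = ssgsea(shuffled, sets, min_size=5, normalize=False)
        pd.testing.assert_frame_equal(a, b)

    def test_location_shift_leaves_scores_unchanged(self):
        rng = np.random.default_rng(5)
        expr = random_expression(rng, 25, 4)
        shifted = ExpressionMatrix(expr.values + 3.7)
        sets = {"A": [f"G{i}" for i in range(8)]}
        pd.testing.assert_frame_equal(
            ssgsea(expr, sets, normalize=False),
            ssgsea(shifted, sets, normalize=False),
        )

    def test_small_set_skipped_with_warning(self):
        rng = np.random.default_rng(6)
        expr = random_expression(rng, 10, 2)
        with pytest.warns(UserWarning, match="skipped"):
            out = ssgsea(expr, {"tiny": ["G0", "G1"]}, min_size=5)
        assert out.empty


class TestLocationEquivariance:
    def test_cyt_and_tis_shift_by_constant(self):
        cfg = SignatureConfig()
        rng = np.random.default_rng(11)
        genes = ["GZMA", "PRF1"] + cfg.tis_gene_list
        df = pd.DataFrame(rng.normal(6, 1, (len(genes), 3)),
                          index=genes, columns=["S0", "S1", "S2"])
        expr = ExpressionMatrix(df)
        shifted = ExpressionMatrix(df + 2.5)
        np.testing.assert_allclose(cyt_score(shifted, cfg),
                                   cyt_score(expr, cfg) + 2.5, atol=1e-12)
        np.testing.assert_allclose(tis_score(shifted, cfg),
                                   tis_score(expr, cfg) + 2.5, atol=1e-12)


class TestEstimateAndPurity:
    def test_purity_closed_form_at_zero_score(self):
        # cos(0.6049872018) evaluated independently = 0.8225093
        assert abs(float(purity_from_estimate(0.0)) - 0.8225093) < 1e-6

    def test_purity_monotone_decreasing_on_valid_domain(self):
        es = np.linspace(0.0, 6000.0, 50)
        p = purity_from_estimate(es)
        assert np.all(np.diff(p[~np.isnan(p)]) < 0)

    def test_purity_undefined_outside_domain(self):
        c0, c1 = 0.6049872018, 0.0001467884
        beyond = (np.pi / 2 - c0) / c1 + 1.0
        assert np.isnan(purity_from_estimate(beyond))
        assert np.isnan(purity_from_estimate((0 - c0) / c1 - 1.0))

    def test_estimate_is_sum_and_purity_matches_transform(self, default_cohort):
        est = estimate_scores(default_cohort.expression)
        np.testing.assert_allclose(
            est["estimate_score"], est["stromal_score"] + est["immune_score"]
        )
        expected = purity_from_estimate(est["estimate_score"].to_numpy())
        np.testing.assert_allclose(est["purity"].to_numpy(), expected)


class TestIPS:
    def test_null_profile_scores_zero(self):
        cfg = SignatureConfig()
        genes = list(cfg.ips_weights["gene"])
        expr = expr_from({g: [5.0, 5.0, 5.0] for g in genes})
        out = immunophenoscore(expr, cfg.ips_weights)
        assert (out["ips"] == 0).all()

    def test_cap_at_ten(self):
        # one extreme sample among many raises its z-scores far above 3
        cfg = SignatureConfig()
        genes = list(cfg.ips_weights["gene"])
        pos = cfg.ips_weights[cfg.ips_weights["weight"] > 0]["gene"]
        neg = cfg.ips_weights[cfg.ips_weights["weight"] < 0]["gene"]
        rows = {}
        for g in genes:
            base = [6.0] * 9
            rows[g] = base + ([60.0] if g in set(pos) else [-60.0] if g in set(neg) else [6.0])
        expr = expr_from(rows)
        out = immunophenoscore(expr, cfg.ips_weights)
        assert out["ips"].iloc[-1] == 10

    def test_discretization_rule(self):
        import math
        for raw, expected in [(-0.5, 0), (0.0, 0), (0.1, 1), (1.5, 5), (3.0, 10), (4.2, 10)]:
            got = 0 if raw <= 0 else min(10, math.ceil(10 * raw / 3))
            assert got == expected


class TestDichotomizeAndTILs:
    def test_even_split(self):
        out = dichotomize_by_median([1.0, 2.0, 3.0, 4.0])
        assert out.tolist() == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        out = dichotomize_by_median([1.0, 2.0, 2.0, 3.0])
        assert out.tolist() == ["low", "low", "low", "high"]

    def test_54_plr_values_split_27_27(self, default_cohort):
        from tnbc_immune.association import compute_ratios

        plr = compute_ratios(default_cohort.cbc).plr
        counts = dichotomize_by_median(plr).value_counts()
        assert counts["low"] == 27 and counts["high"] == 27

    def test_all_identical_warns_all_low(self):
        with pytest.warns(UserWarning):
            out = dichotomize_by_median([2.0, 2.0, 2.0])
        assert (out == "low").all()

    def test_tils_threshold_boundary_inclusive(self):
        out = tils_high_flag([20.0, 19.9, 93.0, 0.0])
        assert out.tolist() == [True, False, True, False]

    def test_tils_out_of_range(self):
        with pytest.raises(ValidationError):
            tils_high_flag([101.0])


class TestPanelOnSyntheticCohort:
    def test_inflamed_cluster_has_highest_cyt_and_tis(self, default_cohort, default_panel):
        med = default_panel.groupby(default_cohort.truth_labels).median()
        assert med["cyt"].idxmax() == "ImA"
        assert med["tis"].idxmax() == "ImA"

    def test_ims_column_is_exact_combination(self, default_panel):
        np.testing.assert_allclose(
            default_panel["ims"],
            default_panel["cyt"] * default_panel["tis"] - default_panel["aggressive"],
            atol=1e-12,
        )
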