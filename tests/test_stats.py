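"""Group statistics: GLM contrasts, BH-FDR, Cohen's d with CI and partial
correlations, each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cestarex.stats import (
    GroupDifferenceModel,
    ROITable,
    analyze_group_table,
    bh_fdr,
    cohens_d_ci,
    glm_group_difference,
    partial_corr,
)


def make_table(wt, arte, covariate=None):
    rows = []
    for i, v in enumerate(wt):
        rows.append({"animal_id": f"WT_{i}", "group": "WT", "m": v})
    for i, v in enumerate(arte):
        rows.append({"animal_id": f"A_{i}", "group": "ARTE10", "m": v})
    df = pd.DataFrame(rows)
    if covariate is not None:
        df["cov"] = covariate
    return ROITable(df)


def brute_force_bh(p):
    """Step-up definition applied literally."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestGroupDifference:
    def test_identical_groups_give_null_result(self):
        table = make_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = glm_group_difference(table, "m")
        assert res.mean_difference == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_covariate_preserves_raw_difference(self):
        # covariate exactly balanced across equal-n groups
        wt, arte = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        cov = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        res = glm_group_difference(make_table(wt, arte, cov), "m", ["cov"])
        raw = np.mean(wt) - np.mean(arte)
        assert res.mean_difference == pytest.approx(raw, abs=1e-12)

    def test_three_row_hand_example(self):
        # WT: 1, 2; ARTE10: 4, plus a WT-sized duplicate for the n>=2 contract
        # is not allowed, so check the pure OLS contrast directly
        y = np.array([1.0, 2.0, 4.0])
        g = np.array([0.0, 0.0, 1.0])
        X = np.column_stack([np.ones(3), g])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert -beta[1] == pytest.approx(-2.5)  # WT − ARTE10
        # and the model reproduces it once both groups have n >= 2
        res = glm_group_difference(make_table([1.0, 2.0], [4.0, 4.0]), "m")
        assert res.mean_difference == pytest.approx(1.5 - 4.0)

    def test_no_covariates_reproduces_pooled_t_test(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            wt = rng.normal(0, 1, 8)
            arte = rng.normal(0.7, 1, 9)
            res = glm_group_difference(make_table(wt, arte), "m")
            t, p = sps.ttest_ind(arte, wt)  # ARTE10 − WT coefficient
            assert res.t == pytest.approx(t, rel=1e-10)
            assert res.p_two_sided == pytest.approx(p, rel=1e-10)
            assert res.df == len(wt) + len(arte) - 2

    def test_collinear_covariate_rejected(self):
        table = make_table([1.0, 2.0], [3.0, 4.0], [0.0, 0.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="singular|collinear"):
            glm_group_difference(table, "m", ["cov"])


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_family(self):
        p = [0.001, 0.011, 0.013, 0.03, 0.18]
        expected = [0.005, 0.021667, 0.021667, 0.0375, 0.18]
        assert np.allclose(bh_fdr(p), expected, atol=1e-6)

    def test_ties_stay_equal(self):
        adj = bh_fdr([0.04, 0.04, 0.04])
        assert np.allclose(adj, 0.04)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])


class TestCohensD:
    def test_hand_computed_value(self):
        d, lo, hi = cohens_d_ci([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert d == pytest.approx(2.0)
        assert lo < d < hi

    def test_identical_groups(self):
        d, lo, hi = cohens_d_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == pytest.approx(0.0)
        assert lo < 0.0 < hi

    def test_label_swap_antisymmetry(self):
        a, b = [1.0, 2.0, 2.5], [3.0, 4.0, 4.5]
        d1, lo1, hi1 = cohens_d_ci(a, b)
        d2, lo2, hi2 = cohens_d_ci(b, a)
        assert d2 == pytest.approx(-d1)
        assert lo2 == pytest.approx(-hi1, abs=1e-6)
        assert hi2 == pytest.approx(-lo1, abs=1e-6)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_ci([1.0, 1.0], [2.0, 2.0])

    def test_ci_brackets_noncentral_t_inversion(self):
        # CI from the noncentral-t must contain d and shrink with n
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 10)
        b = rng.normal(1.0, 1, 10)
        _, lo_small, hi_small = cohens_d_ci(a, b)
        a2, b2 = np.tile(a, 4), np.tile(b, 4)
        _, lo_big, hi_big = cohens_d_ci(a2, b2)
        assert hi_big - lo_big < hi_small - lo_small


class TestPartialCorr:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r, p = partial_corr(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        r, p = partial_corr(x, x.copy())
        assert r == pytest.approx(1.0)

    def test_matches_residual_then_correlate_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.5, 7.0])
        y = np.array([2.0, 1.5, 3.5, 3.0, 6.0, 5.0])
        c = np.array([0.5, 1.0, 1.0, 2.0, 2.5, 3.5])
        X = np.column_stack([np.ones(6), c])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        r_oracle = np.corrcoef(rx, ry)[0, 1]
        r, _ = partial_corr(x, y, c)
        assert r == pytest.approx(r_oracle, abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(15)
        x, y, c = rng.normal(size=(3, 25))
        df = pd.DataFrame({"x": x, "y": y, "c": c})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="c")
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        r, p = partial_corr(x, y, c)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)

    def test_constant_residuals_rejected(self):
        c = np.arange(6, dtype=float)
        x = 2.0 * c + 1.0  # fully explained by the covariate
        y = np.array([2.0, 1.5, 3.5, 3.0, 6.0, 5.0])
        with pytest.raises(ValueError):
            partial_corr(x, y, c)


class TestTableAnalysis:
    def test_family_wide_fdr_and_shape(self):
        rng = np.random.default_rng(21)
        rows = []
        for g, mu in (("WT", 0.0), ("ARTE10", 1.0)):
            for i in range(10):
                rows.append(
                    {
                        "animal_id": f"{g}{i}",
                        "group": g,
                        "m1": rng.normal(mu, 1),
                        "m2": rng.normal(0, 1),
                        "roi_volume": rng.normal(2, 0.2),
                    }
                )
        table = ROITable(pd.DataFrame(rows))
        out = analyze_group_table(table, ["m1", "m2"], ["roi_volume"])
        assert list(out.index) == ["m1", "m2"]
        raw = out["p"].to_numpy()
        assert np.allclose(out["p_fdr"].to_numpy(), brute_force_bh(raw))
        assert (out["d_ci_low"] <= out["cohens_d"]).all()
        assert (out["cohens_d"] <= out["d_ci_high"]).all()

    def test_sign_conventions_are_opposed(self):
        # higher WT mean: positive WT−ARTE10 difference, negative d
        table = make_table([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        res = glm_group_difference(table, "m")
        assert res.mean_difference > 0
        assert res.cohens_d < 0

    def test_duplicate_animal_ids_rejected(self):
        df = pd.DataFrame(
            {
                "animal_id": ["a", "a"],
                "group": ["WT", "ARTE10"],
                "m": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError):
            ROITable(df)
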