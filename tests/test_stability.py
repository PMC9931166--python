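import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special

from discountkit.stability import (
    StabilityAnalysis,
    bf10_pearson,
    classify_bf,
    classify_icc,
    classify_r,
    icc_absolute_agreement,
    pearson_r,
    zscore,
)


def bf10_grid_oracle(r, n, kappa=1.0, m=400_001):
    """Independent dense-grid integration of the Bayes factor.

    Uses plain trapezoid quadrature of the exact r-density times the
    stretched-beta prior, with no adaptive machinery.
    """
    a = 1.0 / kappa
    rho = np.linspace(-1 + 1e-10, 1 - 1e-10, m)

    def loglik(rh):
        return (
            (n - 1) / 2 * np.log1p(-rh**2)
            - (2 * n - 3) / 2 * np.log1p(-rh * r)
            + np.log(special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rh * r + 1) / 2))
        )

    prior = (1 - rho**2) ** (a - 1) / special.beta(a, a) / 2 ** (2 * a - 1)
    vals = np.exp(loglik(rho) - loglik(np.array(0.0))) * prior
    return np.trapezoid(vals, rho)


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = [1.0, 2.0, 4.0, 5.5]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        # r = 3 / sqrt(2 * 14/3) on these points
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(
            3.0 / np.sqrt(2.0 * 14.0 / 3.0)
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestBayesFactor:
    @pytest.mark.parametrize("r,n", [(0.58, 23), (0.63, 23), (0.2, 10), (-0.4, 30), (0.0, 23)])
    def test_matches_dense_grid_oracle(self, r, n):
        got = bf10_pearson(r, n).bf10
        assert got == pytest.approx(bf10_grid_oracle(r, n), rel=1e-6)

    def test_null_favored_at_zero_sample_correlation(self):
        assert bf10_pearson(0.0, 23).bf10 < 1

    def test_sign_symmetric_and_increasing_in_magnitude(self):
        rs = [0.1, 0.3, 0.5, 0.7, 0.9]
        bfs = [bf10_pearson(r, 23).bf10 for r in rs]
        assert np.all(np.diff(bfs) > 0)
        for r in rs:
            assert bf10_pearson(-r, 23).bf10 == pytest.approx(bf10_pearson(r, 23).bf10, rel=1e-9)

    def test_accumulates_with_sample_size(self):
        ns = [10, 20, 40, 80]
        bfs = [bf10_pearson(0.5, n).bf10 for n in ns]
        assert np.all(np.diff(bfs) > 0)

    def test_credible_interval_brackets_r(self):
        bc = bf10_pearson(0.58, 23)
        lo, hi = bc.rho_ci
        assert -1 < lo < 0.58 < hi < 1

    def test_narrower_prior_changes_factor(self):
        assert bf10_pearson(0.63, 23, kappa=0.5).bf10 != pytest.approx(
            bf10_pearson(0.63, 23, kappa=1.0).bf10, rel=1e-3
        )

    @pytest.mark.parametrize("r,n", [(1.0, 23), (0.5, 2)])
    def test_domain_errors(self, r, n):
        with pytest.raises(ValueError):
            bf10_pearson(r, n)


class TestBands:
    @pytest.mark.parametrize(
        "r,band",
        [(0.2, "weak"), (0.35, "weak"), (0.52, "moderate"), (0.67, "moderate"),
         (0.73, "strong"), (0.9, "very strong"), (0.95, "very strong"), (-0.73, "strong")],
    )
    def test_correlation_bands(self, r, band):
        assert classify_r(r) == band

    @pytest.mark.parametrize(
        "bf,band",
        [(14.96, "strong H1"), (24.12, "strong H1"), (5.0, "moderate H1"),
         (1.18, "weak"), (0.5, "weak"), (0.2, "moderate H0"), (0.05, "strong H0")],
    )
    def test_bayes_factor_bands(self, bf, band):
        assert classify_bf(bf) == band

    @pytest.mark.parametrize(
        "icc,band",
        [(0.56, "moderate"), (0.53, "moderate"), (0.62, "moderate"),
         (0.3, "poor"), (0.8, "good"), (0.95, "excellent")],
    )
    def test_icc_bands(self, icc, band):
        assert classify_icc(icc) == band


class TestZscore:
    def test_forced_example(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_unit_sd(self):
        rng = np.random.default_rng(1)
        z = zscore(rng.normal(5, 3, 50))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self):
        v = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        np.testing.assert_allclose(zscore(v), zscore(7 * v - 2), atol=1e-12)


class TestICC:
    def test_identical_columns_give_one(self):
        col = np.array([1.0, 2.5, 3.0, 7.0, -1.0])
        res = icc_absolute_agreement(np.column_stack([col, col, col]))
        assert res.icc == pytest.approx(1.0)
        assert res.pct_between == pytest.approx(100.0)

    def test_independent_columns_give_near_zero(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(200, 3))
        res = icc_absolute_agreement(m)
        assert abs(res.icc) < 0.12

    def test_variance_components_closed_form(self):
        # between-subject and within-subject variance both 1 -> ICC = 0.5
        rng = np.random.default_rng(12)
        subj = rng.normal(0, 1, size=(500, 1))
        m = subj + rng.normal(0, 1, size=(500, 3))
        res = icc_absolute_agreement(m)
        assert res.icc == pytest.approx(0.5, abs=0.06)

    def test_equals_anova_variance_component_form(self):
        # ICC from the single formula equals sigma_b^2/(sigma_b^2+sigma_c^2+
        # sigma_e^2) built from the ANOVA component estimates
        rng = np.random.default_rng(13)
        m = rng.normal(0, 1, size=(40, 3)) + rng.normal(0, 1.5, size=(40, 1))
        res = icc_absolute_agreement(m)
        n, k = res.n_subjects, res.k_raters
        var_b = (res.ms_rows - res.ms_error) / k
        var_c = (res.ms_cols - res.ms_error) / n
        expected = var_b / (var_b + var_c + res.ms_error)
        assert res.icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(14)
        m = rng.normal(0, 1, size=(23, 3)) + rng.normal(0, 1.2, size=(23, 1))
        res = icc_absolute_agreement(m)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(23), 3),
                "rater": np.tile(np.arange(3), 23),
                "score": m.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, "subject", "rater", "score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin rounds its CI bounds to 2 decimals
        assert res.ci95[0] == pytest.approx(row["CI95"][0], abs=6e-3)
        assert res.ci95[1] == pytest.approx(row["CI95"][1], abs=6e-3)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(15)
        m = rng.normal(0, 1, size=(23, 3)) + rng.normal(0, 1, size=(23, 1))
        res = icc_absolute_agreement(m)
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_missing_cells_rejected(self):
        m = np.ones((5, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_absolute_agreement(m)


def _auc_frame(matrices_by_task):
    rows = []
    for task, m in matrices_by_task.items():
        n, k = m.shape
        for i in range(n):
            for t in range(k):
                rows.append(
                    {
                        "participant_id": f"P{i:03d}",
                        "timepoint": t + 1,
                        "task": task,
                        "auc_ord": m[i, t],
                    }
                )
    return pd.DataFrame(rows)


class TestStabilityAnalysis:
    def test_trait_dominated_data_cross_half(self):
        rng = np.random.default_rng(21)
        trait = rng.normal(0, 1.0, size=(40, 1)) + rng.normal(0, 0.4, size=(40, 3))
        state = rng.normal(0, 0.4, size=(40, 1)) + rng.normal(0, 1.0, size=(40, 3))
        res = StabilityAnalysis(_auc_frame({"delay": trait, "effort": state})).fit()
        assert res.iccs["delay"].icc > 0.5
        assert res.iccs["effort"].icc < 0.5

    def test_pooled_zscoring_preserves_mean_shifts(self):
        rng = np.random.default_rng(22)
        base = rng.normal(0, 1, size=(30, 1)) + rng.normal(0, 0.3, size=(30, 3))
        shifted = base + np.array([0.0, 1.5, 3.0])
        frame = _auc_frame({"delay": shifted})
        pooled = StabilityAnalysis(frame, zscore_scope="pooled").fit()
        per_tp = StabilityAnalysis(frame, zscore_scope="per_timepoint").fit()
        # the session shift hurts absolute agreement only under pooled scoring
        assert pooled.iccs["delay"].icc < per_tp.iccs["delay"].icc - 0.2

    def test_retest_entries_cover_all_pairs(self):
        rng = np.random.default_rng(23)
        m = rng.normal(size=(10, 3))
        res = StabilityAnalysis(_auc_frame({"delay": m})).fit()
        assert set(res.retest["delay"]) == {(1, 2), (1, 3), (2, 3)}

    def test_cross_task_section_present(self):
        rng = np.random.default_rng(24)
        res = StabilityAnalysis(
            _auc_frame({"delay": rng.normal(size=(10, 3)), "probability": rng.normal(size=(10, 3))})
        ).fit()
        assert set(res.cross_task) == {1, 2, 3}
        assert ("delay", "probability") in res.cross_task[1]

    def test_incomplete_participant_rejected(self):
        rng = np.random.default_rng(25)
        frame = _auc_frame({"delay": rng.normal(size=(10, 3))})
        with pytest.raises(ValueError, match="incomplete"):
            StabilityAnalysis(frame.iloc[1:]).fit()

    def test_summary_lists_tasks_and_bands(self):
        rng = np.random.default_rng(26)
        m = rng.normal(0, 1, size=(20, 1)) + rng.normal(0, 0.7, size=(20, 3))
        text = StabilityAnalysis(_auc_frame({"delay": m})).fit().summary()
        assert "delay" in text and "ICC" in text
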