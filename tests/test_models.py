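import math

import numpy as np
import pytest

from discountkit import (
    DiscountingModel,
    aicc,
    delta_aicc,
    fit_model,
    median_curve,
    subjective_value,
    support_category,
)
from discountkit.titration import IndifferenceCurve

A = 3000.0
DELAYS = (14, 60, 180, 365, 1095)


def curve(ips, pid="p", tp=1):
    return IndifferenceCurve(pid, tp, "delay", DELAYS, ips, A)


class TestMedianCurve:
    def test_identical_curves_pass_through(self):
        c = curve((2400, 1800, 1000, 600, 250))
        costs, med = median_curve([c, c, c])
        np.testing.assert_allclose(med, c.ips)

    def test_odd_and_even_counts(self):
        cs = [curve((v,) * 5, pid=str(v)) for v in (1000, 2000, 3000)]
        _, med = median_curve(cs)
        np.testing.assert_allclose(med, [2000] * 5)
        _, med = median_curve(cs[:2])
        np.testing.assert_allclose(med, [1500] * 5)

    def test_mismatched_levels_rejected(self):
        a = curve((1, 2, 3, 4, 5))
        b = IndifferenceCurve("q", 1, "delay", (2, 3, 4, 5, 6), (1, 2, 3, 4, 5), A)
        with pytest.raises(ValueError):
            median_curve([a, b])


class TestAicc:
    def test_direct_evaluation(self):
        assert aicc(1.0, 5, 2) == pytest.approx(5 * math.log(0.2) + 4 + 6)

    def test_doubling_rss_adds_n_log_two(self):
        assert aicc(2.0, 5, 2) - aicc(1.0, 5, 2) == pytest.approx(5 * math.log(2))

    def test_correction_term_k3_n5(self):
        # 2k + 2k(k+1)/(n-k-1) = 6 + 24/1
        assert aicc(1.0, 5, 3) - 5 * math.log(0.2) == pytest.approx(30.0)

    def test_zero_rss_flags_minus_infinity(self):
        with pytest.warns(RuntimeWarning):
            assert aicc(0.0, 5, 2) == -math.inf

    def test_undefined_correction_rejected(self):
        with pytest.raises(ValueError):
            aicc(1.0, 4, 3)


class TestDeltaAicc:
    @pytest.mark.parametrize(
        "aiccs,expected",
        [
            # printed comparison triples: delay task, time points 1 and 2
            ((69.93, 68.79, 78.63), (1.14, 0.0, 9.84)),
            ((71.90, 78.56, 83.91), (0.0, 6.66, 12.01)),
            ((5.0, 5.0, 5.0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_subtracts_minimum(self, aiccs, expected):
        got = delta_aicc(aiccs)
        assert min(got) == 0.0
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_translation_invariance(self):
        base = delta_aicc([69.93, 68.79, 78.63])
        shifted = delta_aicc([v + 123.4 for v in (69.93, 68.79, 78.63)])
        np.testing.assert_allclose(base, shifted, atol=1e-9)


class TestSupportCategory:
    @pytest.mark.parametrize(
        "delta,label",
        [
            (0.0, "substantial"),
            (1.14, "substantial"),
            (2.0, "substantial"),
            (5.0, "considerably less"),
            (7.38, "little"),
            (9.84, "little"),
            (12.01, "essentially none"),
        ],
    )
    def test_bands(self, delta, label):
        assert support_category(delta) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            support_category(-0.1)


class TestFitModel:
    def test_recovers_noiseless_hyperbolic_rate(self):
        b_true = 0.05
        ips = [subjective_value("hyperbolic", A, x, b_true) for x in DELAYS]
        fit = fit_model("hyperbolic", DELAYS, ips, A)
        assert fit.b == pytest.approx(b_true, rel=1e-6)
        assert fit.k == 2

    def test_recovers_noiseless_hyperboloid_parameters(self):
        ips = [subjective_value("hyperboloid", A, x, 0.3, 0.6) for x in DELAYS]
        fit = fit_model("hyperboloid", DELAYS, ips, A)
        assert fit.b == pytest.approx(0.3, rel=1e-4)
        assert fit.s == pytest.approx(0.6, rel=1e-4)
        assert fit.k == 3

    def test_flat_curve_drives_rate_to_lower_bound(self):
        for form in ("hyperbolic", "hyperboloid", "power"):
            fit = fit_model(form, DELAYS, [A] * 5, A)
            assert fit.rss == pytest.approx(0.0, abs=1e-12)
            assert fit.b <= 1e-6

    def test_nested_model_never_fits_worse(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            ips = np.sort(rng.uniform(0, A, 5))[::-1]
            rss1 = fit_model("hyperbolic", DELAYS, ips, A).rss
            rss2 = fit_model("hyperboloid", DELAYS, ips, A).rss
            assert rss2 <= rss1 + 1e-10

    def test_extra_parameter_can_lose_on_aicc(self):
        # exact hyperbolic data: hyperboloid gains nothing in rss but pays
        # the larger AICc penalty
        ips = [subjective_value("hyperbolic", A, x, 0.01) for x in DELAYS]
        noisy = [v + d for v, d in zip(ips, (40, -30, 25, -20, 10))]
        f1 = fit_model("hyperbolic", DELAYS, noisy, A)
        f2 = fit_model("hyperboloid", DELAYS, noisy, A)
        assert f2.rss <= f1.rss + 1e-12
        assert f2.aicc > f1.aicc

    def test_fitting_is_deterministic(self):
        ips = (2400, 1700, 900, 500, 200)
        a = fit_model("power", DELAYS, ips, A)
        b = fit_model("power", DELAYS, ips, A)
        assert (a.b, a.s, a.rss) == (b.b, b.s, b.rss)

    def test_rss_is_amount_invariant(self):
        ips = np.array([2400, 1700, 900, 500, 200], dtype=float)
        f1 = fit_model("hyperbolic", DELAYS, ips, A)
        f2 = fit_model("hyperbolic", DELAYS, ips / 3.0, A / 3.0)
        assert f1.rss == pytest.approx(f2.rss, rel=1e-8)
        assert f1.aicc == pytest.approx(f2.aicc, rel=1e-8)


class TestDiscountingModelResults:
    def test_selects_generating_convex_form(self):
        ips = [subjective_value("hyperbolic", A, x, 0.01) for x in DELAYS]
        res = DiscountingModel(DELAYS, ips, A).fit()
        assert res.deltas[res.best_model] == 0.0
        assert res.best_model in ("hyperbolic", "hyperboloid")
        assert res.support_labels[res.best_model] == "substantial"

    def test_concave_data_prefer_power_form(self):
        ips = [subjective_value("power", A, x, 9.0, 0.8) for x in DELAYS]
        res = DiscountingModel(DELAYS, ips, A).fit()
        assert res.best_model == "power"

    def test_aicc_ties_break_toward_fewer_parameters(self):
        # hyperboloid with s=1 reproduces hyperbolic exactly; on such data a
        # tie in AICc must pick the smaller model; merely require best has k=2
        ips = [subjective_value("hyperbolic", A, x, 0.02) for x in DELAYS]
        noisy = [v + d for v, d in zip(ips, (15, -12, 9, -7, 5))]
        res = DiscountingModel(DELAYS, noisy, A).fit()
        assert res.fits[res.best_model].k == 2

    def test_summary_mentions_every_model(self):
        ips = (2400, 1700, 900, 500, 200)
        text = DiscountingModel(DELAYS, ips, A).fit().summary()
        for form in ("hyperbolic", "hyperboloid", "power"):
            assert form in text

    def test_low_noise_cohort_selects_convex_pair(self, study_cohort):
        # hyperbolic generating agents: the hyperbolic/hyperboloid pair gets
        # substantial support in the great majority of task x timepoint cells
        from discountkit.titration import extract_ips

        _, trials, _ = study_cohort
        curves = extract_ips(trials)
        by_key = {}
        for c in curves:
            by_key.setdefault((c.task.value, c.timepoint), []).append(c)
        hits = 0
        for key, group in by_key.items():
            res = DiscountingModel.from_curves(group, amount=A).fit()
            if min(res.deltas["hyperbolic"], res.deltas["hyperboloid"]) <= 2.0:
                hits += 1
        assert hits / len(by_key) >= 0.9
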