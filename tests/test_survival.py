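import numpy as np
import pytest

from sigcore.io import median_center
from sigcore.ssm import ssm_scores
from sigcore.survival import (
    SubtypeFilter,
    cox_hr,
    evaluate_signature,
    km_estimate,
    logrank_counts,
    logrank_p,
    oe_hr,
    oe_hr_from_counts,
    prepare_survival,
    wilcoxon_test,
)
from sigcore.synthetic import SyntheticConfig, generate_cohort

from conftest import make_expr, make_signature


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curves = km_estimate([5, 8, 10], [0, 0, 0], ["g"] * 3)
        assert (curves["g"]["survival"] == 1.0).all()

    def test_two_events_no_censoring_closed_form(self):
        curves = km_estimate([1, 2], [1, 1], ["g", "g"])
        sf = curves["g"].set_index("time")["survival"]
        assert sf.loc[1.0] == pytest.approx(0.5)
        assert sf.loc[2.0] == pytest.approx(0.0)

    def test_five_sample_mixed_censoring_product_limit_by_hand(self):
        # times 1, 2+, 3, 4+, 5 with events at 1, 3, 5:
        # S(1) = 4/5; S(3) = 4/5 * 2/3 = 8/15; S(5) = 0
        curves = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 0, 1], ["g"] * 5)
        sf = curves["g"].set_index("time")["survival"]
        assert sf.loc[1.0] == pytest.approx(4 / 5)
        assert sf.loc[3.0] == pytest.approx(8 / 15)
        assert sf.loc[5.0] == pytest.approx(0.0)

    def test_curves_are_non_increasing_from_one(self, rng):
        t = rng.exponential(10, size=50)
        e = rng.integers(0, 2, size=50)
        curves = km_estimate(t, e, ["g"] * 50)
        s = curves["g"]["survival"].to_numpy()
        assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()


class TestWilcoxon:
    def test_identical_groups_give_p_near_one(self):
        t = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
        g = [0] * 5 + [1] * 5
        assert wilcoxon_test(t, e, g) >= 0.99

    def test_complete_separation_is_significant(self):
        t = list(range(1, 11)) + list(range(20, 30))
        e = [1] * 20
        g = [0] * 10 + [1] * 10
        assert wilcoxon_test(t, e, g) < 0.01

    def test_grouped_logrank_matches_lifelines_risk_tables(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(12, size=60)
        e = rng.integers(0, 2, size=60)
        g = rng.integers(0, 2, size=60).astype(bool)
        prep = prepare_survival(t, e)
        c = logrank_counts(prep, g)
        chi2 = (c["O1"][0] - c["E1"][0]) ** 2 / c["V"][0]
        ref = multivariate_logrank_test(np.maximum(t, 0.01), g.astype(int), e)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)


class TestCox:
    def test_identical_event_patterns_hr_one(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 0, 1, 1, 1, 0]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        assert cox_hr(t, e, g).hr == pytest.approx(1.0, abs=1e-6)

    def test_two_per_group_closed_form_partial_likelihood(self):
        # events: group A at t=1 (risk {2A, 2B}), group B at t=2 (risk {1A, 2B})
        # dL/dr = 0  =>  r = 1/sqrt(2) for B vs A
        res = cox_hr([1, 3, 2, 4], [1, 0, 1, 0], [False, False, True, True])
        assert res.hr == pytest.approx(1 / np.sqrt(2), rel=1e-3)

    def test_no_events_in_group_flagged_not_crashed(self):
        res = cox_hr([1, 2, 3, 4], [1, 1, 0, 0], [0, 0, 1, 1])
        assert not res.estimable
        assert np.isnan(res.hr)

    def test_time_rescaling_invariance(self, rng):
        t = rng.exponential(10, size=80)
        e = rng.integers(0, 2, size=80)
        g = rng.integers(0, 2, size=80).astype(bool)
        a, b = cox_hr(t, e, g), cox_hr(t * 12.0, e, g)
        assert a.hr == pytest.approx(b.hr, rel=1e-8)

    def test_label_swap_inverts_hr_exactly(self, rng):
        t = rng.exponential(10, size=100)
        e = rng.integers(0, 2, size=100)
        g = rng.integers(0, 2, size=100).astype(bool)
        assert cox_hr(t, e, g).hr == pytest.approx(1 / cox_hr(t, e, ~g).hr, rel=1e-6)


class TestOEHazardRatio:
    def test_identical_groups_hr_one(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 1, 1, 1, 1, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        assert oe_hr(t, e, g) == pytest.approx(1.0)

    def test_counts_arithmetic(self):
        assert oe_hr_from_counts(8, 5, 2, 5) == pytest.approx(4.0)

    def test_zero_expected_errors(self):
        with pytest.raises(ValueError):
            oe_hr_from_counts(1, 0.0, 1, 2.0)

    def test_label_swap_inverts_hr_exactly(self, rng):
        t = rng.exponential(10, size=100)
        e = np.ones(100, dtype=int)
        g = rng.integers(0, 2, size=100).astype(bool)
        assert oe_hr(t, e, g) == pytest.approx(1 / oe_hr(t, e, ~g), rel=1e-12)

    def test_close_to_cox_at_large_n(self):
        rng = np.random.default_rng(7)
        n = 2000
        g = rng.random(n) < 0.5
        t = rng.exponential(1.0 / np.where(g, 3.0, 1.0))
        c = rng.uniform(0, 2.0, size=n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        hr_oe = oe_hr(time, event, g)
        hr_cox = cox_hr(time, event, g).hr
        assert hr_oe == pytest.approx(hr_cox, rel=0.15)

    def test_logrank_p_agrees_with_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(10, size=70)
        e = rng.integers(0, 2, size=70)
        g = rng.integers(0, 2, size=70).astype(bool)
        ref = multivariate_logrank_test(np.maximum(t, 0.01), g.astype(int), e)
        assert logrank_p(t, e, g) == pytest.approx(ref.p_value, rel=1e-9)


class TestEvaluateSignature:
    def test_planted_signal_recovered_and_flip_inverts(self):
        cfg = SyntheticConfig(n_samples=400, beta=3.0, seed=11)
        expr, clin, truth = generate_cohort(cfg)
        res = evaluate_signature(expr, clin, cfg.signature, endpoint="MFS")
        assert res.evaluable and res.hr > 1.5 and res.cox_p < 0.01
        flipped = evaluate_signature(expr, clin, cfg.signature.flipped(), endpoint="MFS")
        # 17 genes (odd): no SSM ties, so flipping directions swaps groups exactly
        assert flipped.hr == pytest.approx(1 / res.hr, rel=1e-6)

    def test_subtype_filter_restricts_to_her2_positive(self):
        cfg = SyntheticConfig(n_samples=200, beta=1.0, frac_her2=0.3, seed=13)
        expr, clin, truth = generate_cohort(cfg)
        res = evaluate_signature(
            expr,
            clin,
            cfg.signature,
            subtype=SubtypeFilter(require_her2=True, her2_source="ihc"),
        )
        n_pos = int((clin.df["her2_ihc"] == "positive").sum())
        assert res.n_match + res.n_nomatch == n_pos

    def test_degenerate_split_reports_non_evaluable(self):
        sig = make_signature([("A", 1)])
        expr = make_expr({"A": [5.0, 1.0, 1.0, 1.0]})
        from conftest import make_clinical

        clin = make_clinical(expr.sample_ids, [1, 2, 3, 4], [1, 1, 1, 0])
        res = evaluate_signature(expr, clin, sig)
        assert not res.evaluable
        assert "degenerate" in res.reason
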