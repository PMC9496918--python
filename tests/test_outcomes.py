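import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mtbfocus as m
from mtbfocus.outcomes import logrank_table


def patient(pfs2, event=True, pfs1=3.0, follow_up=None, response=False,
            toxicity=False, pid="p1"):
    return m.PatientOutcome(patient_id=pid, pfs1=pfs1, pfs2=pfs2, event=event,
                            follow_up=pfs2 if follow_up is None else follow_up,
                            clinical_response=response, toxicity_stop=toxicity)


class TestPfsRatio:
    def test_equal_times_give_ratio_one(self):
        assert m.pfs_ratio(4.0, 4.0).report == 1.0

    @pytest.mark.parametrize("pfs2, pfs1, expected", [
        (6, 3.5, 1.7), (23.5, 10.5, 2.2), (7.5, 3, 2.5), (9.5, 1, 9.5),
        (18.5, 3, 6.2), (9.25, 2, 4.6), (6.25, 14, 0.4), (7.7, 1, 7.7),
    ])
    def test_printed_worked_examples(self, pfs2, pfs1, expected):
        assert m.pfs_ratio(pfs2, pfs1).report == expected

    def test_half_up_rounding_convention(self):
        assert m.round_half_up(6.1667, 1) == 6.2
        assert m.round_half_up(4.625, 2) == 4.63
        assert m.round_half_up(0.25, 1) == 0.3  # not banker's

    def test_missing_or_zero_pfs1_is_undefined(self):
        assert str(m.pfs_ratio(12.0, None)) == "n/a"
        assert not m.pfs_ratio(12.0, 0.0).defined
        assert not m.pfs_ratio(12.0, float("nan")).defined

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            m.pfs_ratio(-1.0, 2.0)


class TestClassifyBenefit:
    def test_early_progression_is_no_benefit(self):
        assert m.classify_benefit(patient(1.0)).category == "none"

    def test_six_months_is_major_inclusive(self):
        assert m.classify_benefit(patient(6.0)).category == "major"

    def test_three_months_is_minor_inclusive(self):
        assert m.classify_benefit(patient(3.0)).category == "minor"
        assert m.classify_benefit(patient(4.0)).category == "minor"

    def test_toxicity_stop_is_no_benefit_regardless_of_time(self):
        rec = patient(5.0, toxicity=True)
        assert m.classify_benefit(rec).category == "none"

    def test_response_with_short_follow_up_is_minor(self):
        rec = patient(2.0, event=False, follow_up=2.0, response=True)
        assert m.classify_benefit(rec).category == "minor"

    def test_inconsistent_flags_raise(self):
        with pytest.raises(ValueError, match="inconsistent"):
            m.classify_benefit(patient(5.0, response=True, toxicity=True))

    def test_short_censored_record_not_evaluable(self):
        with pytest.raises(ValueError, match="not evaluable"):
            m.classify_benefit(patient(1.0, event=False))


class TestKaplanMeier:
    def test_hand_computed_product_limit_on_five_observations(self):
        # times 1,2,3,4,5; events 1,1,0,1,0
        # S(1)=4/5, S(2)=4/5*3/4=0.6, S(4)=0.6*1/2=0.3; median 4
        est = m.km_estimate([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        assert est.survival_at(1) == pytest.approx(0.8)
        assert est.survival_at(2) == pytest.approx(0.6)
        assert est.survival_at(3.5) == pytest.approx(0.6)
        assert est.survival_at(4) == pytest.approx(0.3)
        assert est.median == 4

    def test_all_events_at_one_time_drop_to_zero(self):
        est = m.km_estimate([2, 2, 2], [1, 1, 1])
        assert est.survival_at(1.9) == 1.0
        assert est.survival_at(2) == 0.0
        assert est.median == 2

    def test_all_censored_gives_undefined_median(self):
        est = m.km_estimate([1, 2, 3], [0, 0, 0])
        assert est.median is None

    def test_curve_non_increasing_and_matches_empirical_without_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(3, 40)
        est = m.km_estimate(t, np.ones(40, bool))
        assert (np.diff(est.survival) <= 1e-12).all()
        for q in [1.0, 2.0, 5.0]:
            assert est.survival_at(q) == pytest.approx((t > q).mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            m.km_estimate([], [])


class TestLogrank:
    A = ([1, 3, 5, 7], [1, 1, 0, 1])
    B = ([2, 4, 6, 8], [1, 1, 1, 0])

    def test_terms_match_hand_tabulation_on_eight_observations(self):
        table = logrank_table(self.A, self.B)
        assert list(table["d_a"]) == [1, 0, 1, 0, 0, 1]
        assert np.allclose(table["e_a"],
                           [1 / 2, 3 / 7, 1 / 2, 2 / 5, 1 / 3, 1 / 2])
        assert np.allclose(table["var"],
                           [1 / 4, 12 / 49, 1 / 4, 6 / 25, 2 / 9, 1 / 4])

    def test_statistic_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        res = m.logrank_test(self.A, self.B)
        ref = ll_logrank(self.A[0], self.B[0], self.A[1], self.B[1])
        assert res.statistic == pytest.approx(ref.test_statistic)
        assert res.p_value == pytest.approx(ref.p_value)

    def test_identical_arms_give_zero_statistic(self):
        arm = ([1, 2, 3, 4], [1, 1, 1, 0])
        res = m.logrank_test(arm, arm)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        r1 = m.logrank_test(self.A, self.B)
        r2 = m.logrank_test(self.B, self.A)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_no_events_anywhere_is_undefined(self):
        res = m.logrank_test(([1, 2], [0, 0]), ([3], [0]))
        assert not res.defined

    def test_statistic_non_negative(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = (rng.exponential(3, 10), rng.random(10) < 0.8)
            b = (rng.exponential(2, 8), rng.random(8) < 0.8)
            res = m.logrank_test(a, b)
            assert res.statistic >= 0


class TestRankSum:
    def test_single_tied_pair_gives_half(self):
        assert m.ranksum_test([1.0], [1.0]).u == 0.5

    def test_complete_separation_u_equals_product(self):
        res = m.ranksum_test([3, 4, 5], [1, 2, 2.5, 0])
        assert res.u == 12  # |a| * |b|

    def test_u_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 7), rng.normal(0.5, 1, 6)
        res = m.ranksum_test(a, b)
        brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert res.u == brute

    def test_exact_p_matches_full_enumeration(self):
        a, b = [1.2, 3.4, 2.2], [0.5, 2.9, 0.1, 1.0]
        res = m.ranksum_test(a, b)
        assert res.method == "exact"
        pooled = np.array(a + b)
        us = []
        for combo in itertools.combinations(range(7), 3):
            mask = np.zeros(7, bool)
            mask[list(combo)] = True
            x, y = pooled[mask], pooled[~mask]
            us.append(sum((v > w) + 0.5 * (v == w) for v in x for w in y))
        us = np.array(us)
        lo, hi = (us <= res.u).mean(), (us >= res.u).mean()
        assert res.p_value == pytest.approx(min(1.0, 2 * min(lo, hi)))

    def test_exact_p_matches_scipy_without_ties(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
        res = m.ranksum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.u == ref.statistic
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_normal_approximation_matches_scipy_with_ties(self):
        rng = np.random.default_rng(13)
        a = np.round(rng.normal(0, 1, 15), 1)
        b = np.round(rng.normal(0.5, 1, 12), 1)
        res = m.ranksum_test(a, b)
        assert res.method == "normal"
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_u_within_bounds(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            a = rng.integers(0, 5, rng.integers(1, 10)).astype(float)
            b = rng.integers(0, 5, rng.integers(1, 10)).astype(float)
            u = m.ranksum_test(a, b).u
            assert 0 <= u <= len(a) * len(b)


class TestCohortSummary:
    def test_printed_table_percentage(self):
        df = pd.DataFrame({"tumor": ["lower GI"] * 18 + ["other"] * 86})
        out = m.cohort_summary(df, categorical=["tumor"])
        assert out["fields"]["tumor"]["lower GI"] == {"count": 18, "pct": 17.3}

    def test_empty_cohort(self):
        out = m.cohort_summary(pd.DataFrame({"x": []}), categorical=["x"],
                               numeric=["x"])
        assert out["n"] == 0
        assert out["fields"]["x"].get("median", None) is None

    def test_counts_equal_brute_force_tally(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"arm": rng.choice(["matched", "other"], 50),
                           "pfs2": rng.exponential(4, 50)})
        out = m.cohort_summary(df, categorical=["arm"], numeric=["pfs2"])
        for arm in ("matched", "other"):
            assert out["fields"]["arm"][arm]["count"] == int((df["arm"] == arm).sum())
        assert out["fields"]["pfs2"]["median"] == pytest.approx(df["pfs2"].median())

    def test_benefit_table_proportions(self):
        records = ([patient(1.0, pid=f"n{i}") for i in range(9)]
                   + [patient(4.0, pid=f"mi{i}") for i in range(11)]
                   + [patient(7.0, pid=f"ma{i}") for i in range(10)])
        out = m.benefit_table(records)
        assert out["none"] == {"count": 9, "pct": 30.0}
        assert out["minor"] == {"count": 11, "pct": 36.7}
        assert out["major"] == {"count": 10, "pct": 33.3}
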