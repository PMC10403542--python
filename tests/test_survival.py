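"""Kaplan-Meier, log-rank, p-value adjustment and Fisher co-segregation
against direct-formula oracles and lifelines/scipy cross-checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import personall as pa
from personall.survival import CosegDirection, adjust_pvalues, fisher_cosegregation


def _oracle_km(times, events):
    """Literal product-limit loop."""
    out = {}
    s = 1.0
    for t in sorted(set(t for t, e in zip(times, events) if e)):
        n = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei)
        s *= 1 - d / n
        out[t] = s
    return out


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        curve = pa.km_estimate([5.0, 10.0, 20.0], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.surv_at(100.0) == 1.0

    def test_hand_computed_product_limit(self):
        curve = pa.km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
        assert curve.surv_at(1.0) == pytest.approx(2 / 3)
        assert curve.surv_at(2.0) == pytest.approx(1 / 3)
        assert curve.surv_at(3.0) == pytest.approx(1 / 3)

    def test_matches_literal_oracle_with_ties_and_censoring(self):
        rng = np.random.default_rng(5)
        times = np.ceil(rng.exponential(10, 60))
        events = (rng.random(60) < 0.6).astype(int)
        curve = pa.km_estimate(times, events)
        oracle = _oracle_km(list(times), list(events))
        for t, s in oracle.items():
            assert curve.surv_at(t) == pytest.approx(s, abs=1e-12)

    def test_greenwood_zero_before_first_event(self):
        curve = pa.km_estimate([1.0, 5.0, 9.0], [0, 1, 0])
        # the only estimate is at t=5; SE must be positive there but the
        # curve (and so its SE) is exactly 1/0 before any event
        assert curve.surv_at(4.0) == 1.0
        assert (curve.greenwood_se >= 0).all()

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        times = np.ceil(rng.exponential(20, 80))
        events = (rng.random(80) < 0.5).astype(int)
        curve = pa.km_estimate(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in curve.event_times:
            assert curve.surv_at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10)

    def test_five_year_efs_reads_step_at_or_before_60(self):
        curve = pa.km_estimate([12.0, 59.0, 61.0, 70.0], [1, 1, 1, 0])
        # the event at 61 months must not affect the 5-year rate
        assert curve.five_year_efs == pytest.approx(curve.surv_at(59.0))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pa.km_estimate([], [])


def _oracle_logrank_2group(g, times, events):
    """Term-by-term observed-minus-expected / hypergeometric variance."""
    labels = sorted(set(g))
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(t for t, e in zip(times, events) if e)):
        risk = [i for i, ti in enumerate(times) if ti >= t]
        N = len(risk)
        D = sum(1 for i in risk if times[i] == t and events[i])
        n1 = sum(1 for i in risk if g[i] == labels[0])
        d1 = sum(1 for i in risk if g[i] == labels[0] and times[i] == t and events[i])
        o_minus_e += d1 - D * n1 / N
        if N > 1:
            var += D * (n1 / N) * (1 - n1 / N) * (N - D) / (N - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1.0, 2, 3, 1, 2, 3]
        events = [1, 1, 0, 1, 1, 0]
        g = ["a"] * 3 + ["b"] * 3
        chi2, df, p = pa.logrank_test(g, times, events)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_two_group_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(11)
        n = 50
        g = ["a" if i < 25 else "b" for i in range(n)]
        times = list(np.ceil(rng.exponential([8] * 25 + [20] * 25)))
        events = list((rng.random(n) < 0.7).astype(int))
        chi2, df, p = pa.logrank_test(g, times, events)
        assert chi2 == pytest.approx(_oracle_logrank_2group(g, times, events), rel=1e-10)

    def test_triplicated_group_gives_zero(self):
        times = [1.0, 4, 6, 9]
        events = [1, 0, 1, 1]
        g3 = ["a", "b", "c"]
        chi2, df, p = pa.logrank_test(
            [lab for lab in g3 for _ in times], times * 3, events * 3)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 2

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        times = list(np.ceil(rng.exponential(10, 30)))
        events = list((rng.random(30) < 0.6).astype(int))
        g = [str(i % 3) for i in range(30)]
        chi2a, _, _ = pa.logrank_test(g, times, events)
        relabel = {"0": "z", "1": "x", "2": "y"}
        chi2b, _, _ = pa.logrank_test([relabel[x] for x in g], times, events)
        assert chi2a == pytest.approx(chi2b, rel=1e-10)
        # uniform time rescaling preserves ranks, hence the statistic
        chi2c, _, _ = pa.logrank_test(g, [7.3 * t for t in times], events)
        assert chi2a == pytest.approx(chi2c, rel=1e-10)

    def test_matches_lifelines_multigroup(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(17)
        n = 90
        g = [str(i % 3) for i in range(n)]
        scale = {"0": 8.0, "1": 15.0, "2": 30.0}
        times = [float(np.ceil(rng.exponential(scale[x]))) for x in g]
        events = list((rng.random(n) < 0.7).astype(int))
        chi2, df, p = pa.logrank_test(g, times, events)
        ref = multivariate_logrank_test(times, g, events)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            pa.logrank_test(["a", "a"], [1.0, 2.0], [1, 0])


class TestAdjustPvalues:
    def test_bh_worked_example(self):
        got = adjust_pvalues([0.01, 0.02, 0.03])
        assert np.allclose(got, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.2])[0] == pytest.approx(0.2)
        assert adjust_pvalues([0.2], "bonferroni")[0] == pytest.approx(0.2)

    def test_bonferroni_with_declared_m_caps_at_one(self):
        assert adjust_pvalues([0.5], "bonferroni", m=3)[0] == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_bh_monotone_and_bounded_by_bonferroni(self, ps):
        bh = adjust_pvalues(ps)
        bonf = adjust_pvalues(ps, "bonferroni")
        assert (bh <= bonf + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(bh[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.5])


def _oracle_fisher_p(a, b, c, d):
    """Two-sided Fisher p by full enumeration over the hypergeometric
    support (sum of all table probabilities <= the observed one)."""
    n, K, N = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(N, K, n)
    p_obs = rv.pmf(a)
    support = np.arange(max(0, n + K - N), min(n, K) + 1)
    return float(rv.pmf(support)[rv.pmf(support) <= p_obs * (1 + 1e-9)].sum())


class TestFisherCoseg:
    def _matrix(self, a, b, c, d):
        rows = (
            [[True, True]] * a + [[True, False]] * b
            + [[False, True]] * c + [[False, False]] * d
        )
        return pd.DataFrame(rows, columns=["A", "B"])

    def test_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 15, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            res = fisher_cosegregation(self._matrix(a, b, c, d))
            assert res[0].p == pytest.approx(_oracle_fisher_p(a, b, c, d), abs=1e-12)

    def test_zero_overlap_is_mutually_exclusive(self):
        res = fisher_cosegregation(self._matrix(0, 10, 10, 10))[0]
        assert res.p == pytest.approx(_oracle_fisher_p(0, 10, 10, 10), abs=1e-12)
        assert res.odds_ratio < 1
        if res.q < 0.05:
            assert res.direction is CosegDirection.MUTUALLY_EXCLUSIVE

    def test_symmetry_in_lesion_order(self):
        m = self._matrix(8, 3, 5, 20)
        res_ab = fisher_cosegregation(m)[0]
        res_ba = fisher_cosegregation(m[["B", "A"]])[0]
        assert res_ab.p == pytest.approx(res_ba.p, abs=1e-12)

    def test_degenerate_lesion_skipped(self):
        m = self._matrix(5, 5, 5, 5)
        m["ALL"] = True
        res = fisher_cosegregation(m)
        assert {(r.lesion_a, r.lesion_b) for r in res} == {("A", "B")}

    def test_counts_sum_to_cohort_and_q_not_below_p(self, small_cohort):
        _, _, profiles, _ = small_cohort
        X = pa.carrier_matrix(profiles)
        for r in fisher_cosegregation(X):
            assert r.both + r.only_a + r.only_b + r.neither == len(profiles)
            assert r.q >= r.p - 1e-12
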