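import numpy as np
import pytest

import subnetmark as sm
from subnetmark.survival import HIGH, LOW, SurvivalRecord


def recs(rows, group=None):
    return [
        SurvivalRecord(f"p{i}", t, e, group=group)
        for i, (t, e) in enumerate(rows)
    ]


def logrank_textbook(a, b):
    """Independent hypergeometric-expectation log-rank oracle."""
    times = np.array([r.time for r in a] + [r.time for r in b])
    events = np.array([r.event for r in a] + [r.event for r in b])
    in_a = np.array([1] * len(a) + [0] * len(b))
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (in_a == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (in_a == 1)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    from scipy import stats

    return chi2, stats.chi2.sf(chi2, 1)


class TestCompositeScore:
    def _activity(self, rows, ids=None):
        rows = np.asarray(rows, dtype=float)
        ids = ids or [f"S{i}" for i in range(rows.shape[0])]
        samples = [f"s{j}" for j in range(rows.shape[1])]
        return sm.ActivityMatrix(ids, samples, rows)

    def test_single_subnetwork_is_zscore(self):
        act = self._activity([[1.0, 2.0, 3.0, 6.0]])
        got = sm.composite_score(act, ["S0"])
        row = act.scores[0]
        assert np.allclose(got, (row - row.mean()) / row.std())

    def test_identical_rows_equal_single(self):
        act = self._activity([[1.0, 2, 3, 6], [1.0, 2, 3, 6]])
        assert np.allclose(
            sm.composite_score(act, ["S0", "S1"]),
            sm.composite_score(act, ["S0"]),
        )

    def test_matches_mean_of_z_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 20))
        act = self._activity(x)
        orient = {"S0": 2.0, "S1": -3.0, "S2": 1.0, "S3": -0.5}
        got = sm.composite_score(act, list(orient), orient)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        z[1] = -z[1]
        z[3] = -z[3]
        assert np.allclose(got, z.mean(axis=0), atol=1e-12)

    def test_zero_variance_row_excluded(self):
        act = self._activity([[1.0, 1, 1, 1], [0.0, 1, 2, 3]])
        got = sm.composite_score(act, ["S0", "S1"])
        assert np.allclose(got, sm.composite_score(act, ["S1"]))


class TestAssignRiskGroups:
    def test_median_rule(self):
        assert sm.assign_risk_groups([1.0, 2.0, 3.0, 4.0]) == [LOW, LOW, HIGH, HIGH]

    def test_exact_median_goes_low(self):
        groups = sm.assign_risk_groups([1.0, 2.0, 3.0])
        assert groups == [LOW, LOW, HIGH]

    def test_all_equal_degenerate(self):
        assert set(sm.assign_risk_groups([5.0] * 4)) == {LOW}

    def test_odd_count_split(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=101)
        groups = sm.assign_risk_groups(scores)
        assert sum(g == HIGH for g in groups) == 50


class TestKmEstimate:
    def test_no_events_flat(self):
        curve = sm.km_estimate(recs([(5, 0), (8, 0), (10, 0)]))
        assert curve.event_times == [] and curve.survival_prob == []

    def test_all_events_closed_form(self):
        curve = sm.km_estimate(recs([(1, 1), (2, 1), (3, 1)]))
        assert curve.event_times == [1.0, 2.0, 3.0]
        assert np.allclose(curve.survival_prob, [2 / 3, 1 / 3, 0.0])
        assert curve.at_risk == [3, 2, 1]

    def test_hand_computed_table_with_ties_and_censoring(self):
        # records: (5,1),(5,0),(8,1),(8,1),(12,0),(15,1)
        # t=5: n=6, d=1 -> S=5/6 (censored at 5 still at risk at 5)
        # t=8: n=4, d=2 -> S=5/6 * 1/2 = 5/12
        # t=15: n=1, d=1 -> S=0
        curve = sm.km_estimate(recs([(5, 1), (5, 0), (8, 1), (8, 1), (12, 0), (15, 1)]))
        assert curve.event_times == [5.0, 8.0, 15.0]
        assert np.allclose(curve.survival_prob, [5 / 6, 5 / 12, 0.0])
        assert curve.at_risk == [6, 4, 1]

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        times = np.round(rng.exponential(10, 40), 1)
        events = rng.integers(0, 2, 40)
        if events.sum() == 0:
            events[0] = 1
        curve = sm.km_estimate(recs(list(zip(times, events))))
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.event_times, curve.survival_prob):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, 50)
        events = rng.integers(0, 2, 50)
        curve = sm.km_estimate(recs(list(zip(times, events))))
        probs = np.array(curve.survival_prob)
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.all(np.diff(probs) <= 1e-12)
        assert np.all(np.diff(curve.at_risk) <= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(sm.SubnetmarkError):
            SurvivalRecord("p", -1.0, 1)


class TestLogrank:
    def test_identical_groups_null(self):
        rows = [(3, 1), (5, 0), (9, 1)]
        chi2, p = sm.logrank_test(recs(rows), recs(rows))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_swap(self):
        a = recs([(2, 1), (4, 1), (6, 0), (9, 1)])
        b = recs([(1, 1), (3, 0), (5, 1), (7, 1), (11, 0)])
        r1 = sm.logrank_test(a, b)
        r2 = sm.logrank_test(b, a)
        assert r1[0] == pytest.approx(r2[0])
        assert r1[1] == pytest.approx(r2[1])

    def test_matches_textbook_oracle(self):
        a = recs([(2, 1), (4, 1), (4, 0), (6, 1), (9, 0)])
        b = recs([(1, 1), (3, 1), (5, 1), (7, 0), (8, 1)])
        chi2, p = sm.logrank_test(a, b)
        chi2_exp, p_exp = logrank_textbook(a, b)
        assert chi2 == pytest.approx(chi2_exp, abs=1e-8)
        assert p == pytest.approx(p_exp, abs=1e-8)

    def test_time_rescaling_invariance(self):
        a = recs([(2, 1), (4, 1), (6, 0), (9, 1)])
        b = recs([(1, 1), (3, 0), (5, 1), (7, 1)])
        chi2, _ = sm.logrank_test(a, b)
        a2 = recs([(r.time * 7.3, r.event) for r in a])
        b2 = recs([(r.time * 7.3, r.event) for r in b])
        assert sm.logrank_test(a2, b2)[0] == pytest.approx(chi2)

    def test_no_events_convention(self):
        chi2, p = sm.logrank_test(recs([(3, 0)]), recs([(4, 0)]))
        assert (chi2, p) == (0.0, 1.0)


class TestStratifiedAnalysis:
    def _mixed(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = list(zip(rng.exponential(20, n), rng.integers(0, 2, n)))
        out = recs(rows)
        for i, r in enumerate(out):
            r.group = HIGH if i % 2 else LOW
        return out

    def test_single_stratum_equals_unstratified(self):
        records = self._mixed()
        high = [r for r in records if r.group == HIGH]
        low = [r for r in records if r.group == LOW]
        direct = sm.logrank_test(high, low)
        out = sm.stratified_analysis(records)
        assert set(out) == {"all"}
        assert out["all"]["logrank_chi_square"] == pytest.approx(direct[0])

    def test_empty_stratum_omitted(self):
        records = self._mixed()
        strata = {r.sample_id: "er_positive" for r in records}
        out = sm.stratified_analysis(records, strata)
        assert set(out) == {"all", "er_positive"}

    def test_single_group_stratum_skipped(self):
        records = self._mixed()
        strata = {
            r.sample_id: ("solo" if r.group == HIGH else "both")
            for r in records
        }
        out = sm.stratified_analysis(records, strata)
        assert "solo" not in out

    def test_null_er_strata_p_uniformish(self):
        """ER labels independent of risk: stratum p-values are not inflated."""
        rng = np.random.default_rng(20)
        ps = []
        for seed in range(30):
            records = self._mixed(60, seed)
            strata = {
                r.sample_id: ("er_positive" if rng.random() < 0.5 else "er_negative")
                for r in records
            }
            out = sm.stratified_analysis(records, strata)
            for name in ("er_positive", "er_negative"):
                if name in out:
                    ps.append(out[name]["logrank_p"])
        ps = np.array(ps)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01
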