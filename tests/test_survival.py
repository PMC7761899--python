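import numpy as np
import pandas as pd
import pytest

import mammosig as m


def km_oracle(times, events):
    """Brute-force product-limit estimate: S at each distinct event time
    via explicit loops over subjects."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n = sum(ti >= t for ti in times)
        d = sum((ti == t) and (ei == 1) for ti, ei in zip(times, events))
        s *= 1 - d / n
        out[t] = s
    return out


class TestKmCurve:
    def test_all_censored_gives_flat_one(self):
        c = m.km_curve([3.0, 5.0, 8.0], [0, 0, 0])
        assert len(c.event_times) == 0
        assert c.at(100.0) == 1.0

    def test_single_event_among_four(self):
        c = m.km_curve([2.0, 3.0, 4.0, 5.0], [1, 0, 0, 0])
        assert c.at(2.0) == pytest.approx(3 / 4)
        assert c.at(1.9) == 1.0

    def test_eight_subject_mixed_set_matches_hand_oracle(self):
        times = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0]
        events = [1, 1, 0, 1, 1, 0, 0, 1]
        c = m.km_curve(times, events)
        oracle = km_oracle(times, events)
        for t, s in oracle.items():
            assert c.at(t) == pytest.approx(s, abs=1e-12)

    def test_censored_at_event_time_counts_at_risk(self):
        # subject censored exactly at t=2 is in the risk set at t=2
        c = m.km_curve([2.0, 2.0, 3.0], [1, 0, 0])
        assert c.at(2.0) == pytest.approx(2 / 3)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, size=30).round(1)
        c = m.km_curve(times, np.ones(30, int))
        for t in c.event_times:
            assert c.at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_survival_nonincreasing_from_one(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(5, 50)
        events = rng.integers(0, 2, 50)
        c = m.km_curve(times, events)
        if len(c.survival):
            assert c.survival[0] <= 1.0
            assert np.all(np.diff(c.survival) <= 1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            m.km_curve([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = (np.array([1.0, 2, 3, 4]), np.array([1, 1, 0, 1]))
        res = m.logrank([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_event_time_matches_hypergeometric_form(self):
        # groups of 3 and 2 at risk, one event in group A at t=1:
        # E_A = 3/5, V = (1*4/4) * (3/5)(2/5) = 6/25,
        # chi2 = (1 - 3/5)^2 / (6/25) = 2/3
        a = (np.array([1.0, 5.0, 5.0]), np.array([1, 0, 0]))
        b = (np.array([5.0, 5.0]), np.array([0, 0]))
        res = m.logrank([a, b])
        assert res.statistic == pytest.approx((0.4 ** 2) / (6 / 25))
        assert res.observed.sum() == pytest.approx(res.expected.sum())

    def test_observed_equals_expected_in_total(self):
        rng = np.random.default_rng(2)
        groups = [
            (rng.exponential(5, 40), rng.integers(0, 2, 40)) for _ in range(3)
        ]
        res = m.logrank(groups)
        assert res.observed.sum() == pytest.approx(res.expected.sum(), abs=1e-9)

    def test_two_group_statistic_equals_squared_trend_01(self):
        rng = np.random.default_rng(3)
        a = (rng.exponential(5, 30), rng.integers(0, 2, 30))
        b = (rng.exponential(9, 25), rng.integers(0, 2, 25))
        plain = m.logrank([a, b])
        trend = m.logrank([a, b], trend_scores=[0.0, 1.0])
        assert plain.statistic == pytest.approx(trend.statistic, rel=1e-9)

    def test_matches_lifelines_multivariate(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(4)
        groups = [
            (rng.exponential(5 + 3 * g, 35), rng.integers(0, 2, 35))
            for g in range(3)
        ]
        res = m.logrank(groups)
        t = np.concatenate([g[0] for g in groups])
        e = np.concatenate([g[1] for g in groups])
        lab = np.concatenate([[g] * 35 for g in range(3)])
        ll = multivariate_logrank_test(t, lab, e)
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-6)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-6)

    def test_zero_events_warns_p_one(self):
        a = (np.array([1.0, 2.0]), np.array([0, 0]))
        b = (np.array([3.0, 4.0]), np.array([0, 0]))
        with pytest.warns(UserWarning, match="no events"):
            res = m.logrank([a, b])
        assert res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            m.logrank([(np.array([1.0]), np.array([1]))])


class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        g = (np.array([1.0, 2, 3, 4, 5]), np.array([1, 1, 1, 0, 1]))
        res = m.hazard_ratio(g, g)
        assert res.hr == pytest.approx(1.0)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_reciprocity(self):
        rng = np.random.default_rng(5)
        a = (rng.exponential(5, 40), rng.integers(0, 2, 40))
        b = (rng.exponential(12, 40), rng.integers(0, 2, 40))
        ab = m.hazard_ratio(a, b)
        ba = m.hazard_ratio(b, a)
        assert ab.hr * ba.hr == pytest.approx(1.0, abs=1e-12)
        assert ab.ci_low == pytest.approx(1 / ba.ci_high, abs=1e-12)

    def test_true_threefold_hazard_recovered(self):
        cfg = m.BulkSimConfig(
            n_tumors=400, purity=1.0, noise_sd=0.1, censor_rate=0.1, seed=6,
            hazard_multipliers={"tA": 1.0, "tB": 3.0},
        )
        profiles = pd.DataFrame(
            np.random.default_rng(0).uniform(0, 8, size=(10, 2)),
            index=[f"G{i}" for i in range(10)], columns=["tA", "tB"],
        )
        _, clin, truth = m.simulate_bulk(cfg, profiles)
        gen = truth.generating_type_of_tumor.to_numpy()
        grp = lambda t: (
            clin.loc[gen == t, "os_time"].to_numpy(),
            clin.loc[gen == t, "os_event"].to_numpy(),
        )
        res = m.hazard_ratio(grp("tB"), grp("tA"))
        assert 2.2 <= res.hr <= 4.0

    def test_zero_events_rejected(self):
        a = (np.array([1.0]), np.array([0]))
        with pytest.raises(ValueError):
            m.hazard_ratio(a, a)


class TestSurvivalByCluster:
    def _records(self, seed=7):
        rng = np.random.default_rng(seed)
        n = 90
        clusters = rng.choice(["c7", "c8", "c9"], size=n)
        rate = np.where(clusters == "c9", 0.3, 0.1)
        return pd.DataFrame(
            {
                "sample": [f"T{i}" for i in range(n)],
                "assigned_cluster": clusters,
                "subtype": "TNBC",
                "os_time": rng.exponential(1 / rate),
                "os_event": rng.integers(0, 2, n),
            }
        )

    def test_single_cluster_after_filter_rejected(self):
        rec = self._records()
        with pytest.raises(ValueError, match="two clusters"):
            m.survival_by_cluster(rec, clusters=["c7"])

    def test_high_hazard_cluster_has_lower_curve_and_hr_near_truth(self):
        rng = np.random.default_rng(8)
        n = 400
        clusters = rng.choice(["c7", "c9"], size=n)
        rate = np.where(clusters == "c9", 0.3, 0.1)
        rec = pd.DataFrame(
            {
                "sample": [f"T{i}" for i in range(n)],
                "assigned_cluster": clusters,
                "subtype": "TNBC",
                "os_time": rng.exponential(1 / rate),
                "os_event": 1,
            }
        )
        rep = m.survival_by_cluster(rec, subtype_filter="TNBC",
                                    reference="c7")
        t = np.median(rec["os_time"])
        assert rep.curves["c9"].at(t) < rep.curves["c7"].at(t)
        hr = rep.hazard_ratios.set_index("cluster").loc["c9", "hr"]
        assert 2.2 <= hr <= 4.0
        assert rep.logrank.p_value < 0.01

    def test_report_contains_trend_and_pairwise_hrs(self):
        rep = m.survival_by_cluster(self._records(), subtype_filter="TNBC",
                                    reference="c7")
        assert rep.trend.df == 1
        assert set(rep.hazard_ratios["cluster"]) == {"c8", "c9"}
        assert len(rep.curves) == 3
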