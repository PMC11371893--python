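"""Statistical pipeline against exhaustive/hand-computed oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from coroqca.errors import AnalysisError, SchemaError
from coroqca.stats import (
    AnalysisConfig,
    compare_groups,
    km_hazard,
    roc_delong,
    run_full_analysis,
    spearman_corr,
    youden_cutoff,
)


def _cohort_frame(fcl, ncl, metric="x"):
    rows = [{"group": "FCL", metric: v} for v in fcl] + [
        {"group": "NCL", metric: v} for v in ncl
    ]
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_exact_small_sample_p(self):
        # U = 0 for fully separated {1,2,3} vs {4,5,6}; exhaustive permutation
        # over C(6,3) = 20 orderings gives two-sided p = 2/20 = 0.1
        res = compare_groups(_cohort_frame([1, 2, 3], [4, 5, 6]), ["x"])[0]
        assert res.u_statistic == 0
        assert res.p_raw == pytest.approx(0.1)

    def test_exhaustive_permutation_oracle_small_n(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            res = compare_groups(_cohort_frame(x, y), ["x"])[0]
            # oracle: enumerate all label assignments, count U as extreme
            pooled = np.concatenate([x, y])
            u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
            m = len(x)
            us = []
            for comb in itertools.combinations(range(len(pooled)), m):
                xs = pooled[list(comb)]
                ys = np.delete(pooled, list(comb))
                us.append(sum((a > b) + 0.5 * (a == b) for a in xs for b in ys))
            us = np.asarray(us)
            mean_u = m * (len(pooled) - m) / 2
            p_exact = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
            assert res.p_raw == pytest.approx(p_exact, abs=1e-9)

    def test_identical_groups_p_one(self):
        vals = list(np.linspace(0, 1, 20))
        res = compare_groups(_cohort_frame(vals, vals), ["x"])[0]
        assert res.p_raw > 0.95

    def test_bonferroni_cap(self):
        x = np.linspace(0, 1, 30)
        y = x + 0.05
        res = compare_groups(_cohort_frame(x, y), ["x"], bonferroni_m=9)[0]
        assert res.p_adjusted == min(1.0, 9 * res.p_raw)
        assert res.p_adjusted >= res.p_raw

    def test_bonferroni_never_rejects_more(self, rng):
        alpha = 0.05
        for _ in range(5):
            df = _cohort_frame(rng.normal(size=30), rng.normal(0.5, 1, size=30))
            res = compare_groups(df, ["x"], bonferroni_m=9)[0]
            if res.p_adjusted <= alpha:
                assert res.p_raw <= alpha

    def test_empty_group_raises(self):
        df = _cohort_frame([1, 2, 3], [])
        with pytest.raises(AnalysisError):
            compare_groups(df, ["x"])


class TestSpearman:
    def test_perfectly_monotone(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [10, 20, 30, 40, 50]})
        assert spearman_corr(df, [("a", "b")])[0].rho == pytest.approx(1.0)

    def test_antimonotone(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [-1, -2, -3, -4, -5]})
        assert spearman_corr(df, [("a", "b")])[0].rho == pytest.approx(-1.0)

    def test_hand_rank_computation(self):
        # d = ranks difference, sum d^2 = 8, r = 1 - 6*8/(5*24) = 0.6
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [3, 1, 2, 5, 4]})
        assert spearman_corr(df, [("a", "b")])[0].rho == pytest.approx(0.6)

    def test_constant_column_raises(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 2, 2, 2]})
        with pytest.raises(AnalysisError):
            spearman_corr(df, [("a", "b")])


class TestRocDelong:
    def test_perfect_separation(self):
        r = roc_delong([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], "high")
        assert r.auc == 1.0

    def test_pair_counting_example(self):
        r = roc_delong([1, 1, 0, 0], [0.9, 0.6, 0.7, 0.2], "high")
        assert r.auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        r = roc_delong([1, 1, 0, 0], [0.5, 0.5, 0.5, 0.5], "high")
        assert r.auc == pytest.approx(0.5)

    def test_matches_exhaustive_pair_counting(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 51))
            y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            s = np.round(rng.normal(size=n), 1)  # rounded -> ties occur
            r = roc_delong(y, s, "high")
            pos, neg = s[y == 1], s[y == 0]
            pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg]
            assert r.auc == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=200)
        y[:3] = [0, 1, 0]  # both classes
        s = rng.normal(size=200)
        assert roc_delong(y, s, "high").auc == pytest.approx(
            roc_auc_score(y, s), abs=1e-12
        )

    def test_orientation_flip_invariance(self, rng):
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        s = rng.normal(size=100)
        a = roc_delong(y, s, "high")
        b = roc_delong(y, -s, "low")
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.variance == pytest.approx(b.variance, abs=1e-15)

    def test_one_class_absent_raises(self):
        with pytest.raises(AnalysisError):
            roc_delong([1, 1, 1], [0.1, 0.2, 0.3], "high")

    def test_delong_ci_coverage(self, rng):
        """Coverage of the 95% CI over two-Gaussian simulations with the
        closed-form true AUC Φ(Δμ/√(σ1²+σ2²))."""
        from scipy.stats import norm as normal

        mu = 1.0
        true_auc = normal.cdf(mu / np.sqrt(2.0))
        n_sim, covered = 1000, 0
        for _ in range(n_sim):
            pos = rng.normal(mu, 1, size=80)
            neg = rng.normal(0, 1, size=108)
            r = roc_delong(
                np.r_[np.ones(80, int), np.zeros(108, int)], np.r_[pos, neg], "high"
            )
            covered += r.ci_low <= true_auc <= r.ci_high
        assert 0.92 <= covered / n_sim <= 0.98


class TestYouden:
    def test_separated_groups_midpoint(self):
        r = youden_cutoff([1, 1, 0, 0], [0.2, 0.3, 0.6, 0.7], "low")
        assert r.threshold == pytest.approx(0.45)
        assert r.youden_j == pytest.approx(1.0)
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_identical_distributions_j_zero(self):
        r = youden_cutoff([1, 0, 1, 0], [0.4, 0.4, 0.6, 0.6], "high")
        assert r.youden_j == pytest.approx(0.0)

    def test_single_distinct_score_raises(self):
        with pytest.raises(AnalysisError):
            youden_cutoff([1, 0], [0.5, 0.5], "high")

    def test_matches_brute_force_over_thresholds(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0], y[-1] = 0, 1
            s = np.round(rng.normal(size=n), 1)
            if len(np.unique(s)) < 2:
                continue
            r = youden_cutoff(y, s, "high")
            pos, neg = s[y == 1], s[y == 0]
            best_j = max(
                np.mean(pos > t) + np.mean(neg <= t) - 1
                for t in np.linspace(s.min() - 1, s.max() + 1, 500)
            )
            assert r.youden_j == pytest.approx(best_j, abs=1e-9)

    def test_orientation_flip_invariance(self, rng):
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        s = rng.normal(size=60)
        a = youden_cutoff(y, s, "high")
        b = youden_cutoff(y, -s, "low")
        assert a.youden_j == pytest.approx(b.youden_j, abs=1e-12)
        # the same vessels are classified as high-risk under both encodings
        assert np.array_equal(s > a.threshold, -s < b.threshold)


def _survival_frame(times_a, events_a, times_b, events_b):
    return pd.DataFrame(
        {
            "x": np.r_[np.zeros(len(times_a)), np.ones(len(times_b))],
            "time_months": np.r_[times_a, times_b],
            "event": np.r_[events_a, events_b],
        }
    )


class TestKmHazard:
    def test_hand_product_limit(self):
        # stratum low (x < 0.5): times 1,2,3 all events -> S = 2/3, 1/3, 0
        df = _survival_frame([1, 2, 3], [1, 1, 1], [1, 2, 3], [0, 0, 0])
        res = km_hazard(df, "x", 0.5)
        low = res.curves["low"]
        assert low["survival"][-3:] == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert res.curves["high"]["survival"] == pytest.approx([1.0, 1.0, 1.0, 1.0])

    def test_km_equals_empirical_without_censoring(self, rng):
        times = rng.exponential(10, size=60).round(2) + 0.01
        df = _survival_frame(times, np.ones(60, int), times + 1, np.ones(60, int))
        res = km_hazard(df, "x", 0.5)
        t_grid = np.array(res.curves["low"]["time"])
        surv = np.array(res.curves["low"]["survival"])
        emp = np.array([(times > t).mean() for t in t_grid])
        assert np.allclose(surv, emp, atol=1e-12)

    def test_identical_strata_hr_one(self, rng):
        times = rng.exponential(10, size=80) + 0.1
        events = rng.integers(0, 2, size=80)
        events[:2] = 1
        df = _survival_frame(times, events, times, events)
        res = km_hazard(df, "x", 0.5)
        assert res.hazard_ratio == pytest.approx(1.0, abs=0.05)
        assert res.logrank_p > 0.9

    def test_cox_recovers_doubled_hazard(self, rng):
        n = 2000
        fast = rng.exponential(0.5, size=n)  # rate 2
        slow = rng.exponential(1.0, size=n)  # rate 1
        df = _survival_frame(fast, np.ones(n, int), slow, np.ones(n, int))
        res = km_hazard(df, "x", 0.5)  # low stratum = fast
        assert 1.8 <= res.hazard_ratio <= 2.2
        assert res.hr_ci_low > 1.0

    def test_empty_stratum_raises(self):
        df = _survival_frame([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 0, 1])
        with pytest.raises(AnalysisError):
            km_hazard(df, "x", -5.0)

    def test_no_events_raises(self):
        df = _survival_frame([1, 2], [0, 0], [3, 4], [0, 0])
        with pytest.raises(AnalysisError):
            km_hazard(df, "x", 0.5)


class TestRunFullAnalysis:
    def test_report_schema_on_default_cohort(self, default_table):
        report = run_full_analysis(default_table)
        assert len(report.comparisons) == 9  # the Table-1 metric list
        assert {c.metric for c in report.comparisons} == {
            "MLR", "MLA", "PROXA", "DISTA", "LLR", "PLSL", "LSL", "dvffr", "vffr",
        }
        assert "any_mi" in report.roc and len(report.roc["any_mi"]) == 9
        assert {"stemi", "nstemi"} <= set(report.roc)
        assert report.survival["any_mi"][0].metric == "MLR"
        payload = report.to_dict()
        import json

        json.dumps(payload)  # must be serialisable

    def test_single_group_partial_failure(self, default_table):
        solo = default_table[default_table.group == "FCL"]
        report = run_full_analysis(solo)
        assert "comparisons" in report.errors
        assert report.group_medians  # descriptive summaries still emitted

    def test_missing_columns_schema_error(self):
        with pytest.raises(SchemaError, match="missing"):
            run_full_analysis(pd.DataFrame({"MLR": [1, 2]}))

    def test_zero_stemi_panel_skipped(self, default_table):
        t = default_table.copy()
        t["mi_type"] = "NSTEMI"
        with pytest.warns(UserWarning, match="STEMI"):
            report = run_full_analysis(t)
        assert "stemi" not in report.roc
        assert "roc_stemi" in report.errors
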