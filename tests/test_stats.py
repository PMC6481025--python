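"""Tests for the cohort statistics: rank tests, regressions, study report."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ocutort.stats import (
    StatsConfig,
    SubjectRecord,
    aggregate_to_subject,
    load_fabry_cohort,
    mann_whitney,
    ols_regression,
    run_study,
    summarize_demographics,
)


def enumeration_p(x, y):
    """Independent exact oracle: two-sided p by brute-force rank splits."""
    pooled = np.concatenate((x, y))
    n1, n = len(x), len(pooled)
    order = pooled.argsort()
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = [
        sum(combo) - n1 * (n1 + 1) / 2
        for combo in itertools.combinations(range(1, n + 1), n1)
    ]
    us = np.array(us, float)
    one = min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean())
    return min(1.0, 2 * one)


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_u_statistics_sum_to_n1n2(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=5)
        ux = mann_whitney(x, y).statistic
        uy = mann_whitney(y, x).statistic
        assert ux + uy == pytest.approx(35)

    def test_swap_invariance(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=9)
        assert mann_whitney(x, y).p_value == pytest.approx(
            mann_whitney(y, x).p_value, abs=1e-12
        )

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (5, 4), (6, 3)])
    def test_exact_matches_enumeration_oracle(self, n1, n2, rng):
        for _ in range(5):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_exact_matches_scipy_exact(self, rng):
        # independent library oracle on untied data
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            ours = mann_whitney(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_close_to_normal_approx_at_n8(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        exact = mann_whitney(x, y)
        assert exact.method == "exact"
        from ocutort.stats import _mann_whitney

        approx = _mann_whitney(x, y, exact_threshold=0)
        assert approx.method == "normal_approx_tie_corrected"
        assert exact.p_value == pytest.approx(approx.p_value, abs=0.01)

    def test_ties_use_corrected_approximation(self):
        res = mann_whitney([1, 1, 2, 5], [2, 2, 3, 3])
        assert res.method == "normal_approx_tie_corrected"
        ref = mannwhitneyu([1, 1, 2, 5], [2, 2, 3, 3], alternative="two-sided",
                           method="asymptotic", use_continuity=True)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestOLS:
    def test_perfect_fit(self):
        x = np.arange(5.0)
        res = ols_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response(self):
        res = ols_regression(np.arange(6.0), np.full(6, 3.0))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=20)
        y = 1.5 * x + rng.normal(size=20)
        res = ols_regression(x, y)
        X = np.column_stack((np.ones(20), x))
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (20 - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.slope_se == pytest.approx(se, abs=1e-10)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            ols_regression(np.ones(5), np.arange(5.0))


class TestDemographics:
    def test_fabry_case_series_summary(self):
        # published clinical table: 11 patients, mean age 51.7 (SD 15.6),
        # range 30-71, 5 males / 6 females
        df = load_fabry_cohort()
        records = [
            SubjectRecord(subject_id=r.subject_id, group=r.group, sex=r.sex, age=r.age)
            for r in df.itertuples()
        ]
        s = summarize_demographics(records)["FD"]
        assert s["n"] == 11
        assert (s["n_male"], s["n_female"]) == (5, 6)
        assert round(s["age_mean"], 1) == 51.7
        assert round(s["age_sd"], 1) == 15.6
        assert (s["age_min"], s["age_max"]) == (30, 71)

    def test_single_subject_sd_missing(self):
        s = summarize_demographics(
            [SubjectRecord(subject_id="a", group="FD", sex="M", age=40)]
        )
        assert s["FD"]["age_sd"] is None

    def test_record_validation(self):
        with pytest.raises(ValueError):
            SubjectRecord(subject_id="x", group="FD", sex="M", age=40, nyha=5)
        with pytest.raises(ValueError):
            SubjectRecord(subject_id="x", group="patients", sex="M", age=40)


def _metrics_df(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "eye", "site", "segment_id", "soam", "pad", "i2e"]
    )


class TestAggregation:
    def test_mean_of_eye_means(self):
        rows = [("s1", "OD", "retina", f"seg{i}", v, v, 1.0)
                for i, v in enumerate([0.10, 0.12, 0.14, 0.10, 0.09])]
        rows += [("s1", "OS", "retina", f"seg{i}", v, v, 1.0)
                 for i, v in enumerate([0.11, 0.13, 0.15, 0.11, 0.10])]
        agg = aggregate_to_subject(_metrics_df(rows))
        od = np.mean([0.10, 0.12, 0.14, 0.10, 0.09])
        os_ = np.mean([0.11, 0.13, 0.15, 0.11, 0.10])
        assert agg.loc[0, "soam"] == pytest.approx((od + os_) / 2)

    def test_single_eye_warns(self):
        rows = [("s1", "OD", "retina", "seg1", 0.1, 0.5, 1.01),
                ("s1", "OD", "retina", "seg2", 0.2, 0.6, 1.02)]
        with pytest.warns(UserWarning, match="single eye"):
            agg = aggregate_to_subject(_metrics_df(rows))
        assert agg.loc[0, "soam"] == pytest.approx(0.15)

    def test_eye_mode(self):
        rows = [("s1", "OD", "retina", "seg1", 0.1, 0.5, 1.01),
                ("s1", "OS", "retina", "seg1", 0.3, 0.7, 1.03)]
        agg = aggregate_to_subject(_metrics_df(rows), mode="eye")
        assert len(agg) == 2


def _tiny_cohort(with_gfr=True):
    records, metrics = [], []
    rng = np.random.default_rng(17)
    for g, shift in (("FD", 0.05), ("control", 0.0)):
        for i in range(5):
            sid = f"{g}{i}"
            records.append(
                SubjectRecord(
                    subject_id=sid, group=g, sex="M" if i % 2 else "F",
                    age=40.0 + i, gfr=(80.0 + i if with_gfr and g == "FD" else None),
                    mwt=(10.0 + i if g == "FD" else None),
                )
            )
            for eye in ("OD", "OS"):
                for site in ("retina", "conj_nasal"):
                    for k in range(2):
                        base = 0.1 + shift + 0.01 * rng.normal()
                        metrics.append(
                            (sid, eye, site, f"seg{k}", base, base * 5, 1.0 + base / 10)
                        )
    return records, _metrics_df(metrics)


class TestRunStudy:
    def test_all_comparisons_present(self):
        records, metrics = _tiny_cohort()
        report = run_study(metrics, records)
        frame = report.tests_frame()
        # 2 sites x 3 metrics group tests
        assert len(report.group_tests) == 6
        # M vs F within each group at each site/metric
        assert len(report.sex_tests) == 12
        assert {"comparison", "p_value", "significant"} <= set(frame.columns)
        assert len(report.retina_conjunctiva) == 3
        assert report.demographics["FD"]["n"] == 5

    def test_missing_gfr_skipped_with_reason(self):
        records, metrics = _tiny_cohort(with_gfr=False)
        report = run_study(metrics, records)
        skipped = [s for s in report.skipped if "gfr" in s["comparison"]]
        assert skipped and all(s["reason"] for s in skipped)

    def test_unknown_subject_rejected(self):
        records, metrics = _tiny_cohort()
        metrics.loc[0, "subject_id"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            run_study(metrics, records)

    def test_report_json_round_trip(self):
        import json

        records, metrics = _tiny_cohort()
        report = run_study(metrics, records, StatsConfig(alpha=0.05))
        payload = json.loads(report.to_json())
        assert payload["alpha"] == 0.05
        assert len(payload["group_tests"]) == 6
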