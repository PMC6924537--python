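"""Outlier screening, t-tests, paired contrasts and covariate regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from connectopharm.stats import (
    DEFAULT_REPORT_METRICS,
    build_study_table,
    covariate_regression,
    disease_effect_report,
    paired_drug_contrast,
    remove_outliers,
    two_sample_ttest,
    two_sample_ttest_from_stats,
)

from oracles import permutation_ttest_p


class TestRemoveOutliers:
    def test_single_extreme_value_removed(self):
        vals = [0.0] * 9 + [20.0]
        kept, removed = remove_outliers(pd.Series(vals))
        # mean 2, SD 6.32 -> z(20) = 2.85 > 2
        assert removed == [9]
        assert len(kept) == 9

    def test_identical_values_all_kept(self):
        kept, removed = remove_outliers(pd.Series([3.0] * 6))
        assert removed == []
        assert len(kept) == 6

    def test_symmetric_data_untouched(self):
        kept, removed = remove_outliers(pd.Series([-1.0, -0.5, 0.0, 0.5, 1.0]))
        assert removed == []

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            remove_outliers(pd.Series([1.0, 2.0]))


class TestTwoSampleTTest:
    def test_identical_groups(self):
        res = two_sample_ttest([1.0, 1.0, 1.0], [1.0, 1.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_baseline_stop_signal_difference(self):
        # patients 198 (73) n=30 vs controls 164 (39) n=75, Welch
        res = two_sample_ttest_from_stats(198, 73, 30, 164, 39, 75)
        assert res.p == pytest.approx(0.02, abs=0.01)

    def test_matches_scipy_data_form(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 20)
        mine = two_sample_ttest(a, b, variant="welch")
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_agrees_with_permutation_oracle(self, rng):
        for seed in range(3):
            local = np.random.default_rng(seed)
            a = local.normal(0.0, 1.0, 15)
            b = local.normal(0.6, 1.0, 15)
            p_perm = permutation_ttest_p(a, b, n_perm=20_000, seed=seed)
            p_t = two_sample_ttest(a, b, variant="pooled").p
            assert p_t == pytest.approx(p_perm, abs=0.01)


def _toy_table():
    rows = []
    for i in range(6):
        sid = f"p{i}"
        for session, val in (("placebo", 1.0 + i), ("atomoxetine", 2.5 + i)):
            rows.append(
                {
                    "subject_id": sid,
                    "group": "patient",
                    "session": session,
                    "metric": "clustering",
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


class TestPairedContrast:
    def test_constant_shift(self):
        delta = paired_drug_contrast(_toy_table(), "clustering", "atomoxetine")
        assert np.allclose(delta, 1.5)

    def test_identical_sessions_zero(self):
        t = _toy_table()
        t.loc[t.session == "atomoxetine", "value"] = (
            t.loc[t.session == "placebo", "value"].to_numpy()
        )
        delta = paired_drug_contrast(t, "clustering", "atomoxetine")
        assert np.allclose(delta, 0.0)

    def test_missing_session_dropped(self, caplog):
        t = _toy_table()
        t = t[~((t.subject_id == "p3") & (t.session == "atomoxetine"))]
        with caplog.at_level("INFO"):
            delta = paired_drug_contrast(t, "clustering", "atomoxetine")
        assert len(delta) == 5
        assert "p3" not in delta.index
        assert "p3" in caplog.text

    def test_no_pairs_is_error(self):
        t = _toy_table()
        with pytest.raises(ValueError):
            paired_drug_contrast(t[t.session == "placebo"], "clustering", "citalopram")


class TestCovariateRegression:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = covariate_regression(2.0 * x, x)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(0, 2, 25)
            y = 0.7 * x + rng.normal(0, 1, 25)
            res = covariate_regression(y, x)
            # independent closed-form least squares
            xc, yc = x - x.mean(), y - y.mean()
            slope = (xc @ yc) / (xc @ xc)
            r2 = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))
            n = len(x)
            se = np.sqrt(((yc - slope * xc) @ (yc - slope * xc)) / (n - 2) / (xc @ xc))
            p = 2 * sps.t.sf(abs(slope / se), n - 2)
            assert res.slope == pytest.approx(slope, abs=1e-10)
            assert res.r_squared == pytest.approx(r2, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_regression_type1_error_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = rng.standard_normal(30)
            x = rng.standard_normal(30)
            rejections += covariate_regression(y, x).p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            covariate_regression(np.arange(6.0), np.ones(6))

    def test_too_few_cases(self):
        with pytest.raises(ValueError, match="4 complete"):
            covariate_regression([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestDiseaseReport:
    def _study(self, rng, shift=0.0):
        rows = []
        for group, n, tag in (("control", 20, "c"), ("patient", 12, "p")):
            for i in range(n):
                for metric in DEFAULT_REPORT_METRICS:
                    rows.append(
                        {
                            "subject_id": f"{tag}{i}",
                            "group": group,
                            "session": "none" if group == "control" else "placebo",
                            "metric": metric,
                            "value": rng.standard_normal()
                            - (shift if group == "patient" else 0.0),
                        }
                    )
        return pd.DataFrame(rows)

    def test_contains_the_headline_comparisons(self, rng):
        df = self._study(np.random.default_rng(1))
        report = disease_effect_report(
            df[df.group == "control"], df[df.group == "patient"]
        )
        assert set(report.metric) == set(DEFAULT_REPORT_METRICS)
        assert (report.correction == "none (network measures are not independent)").all()

    def test_null_groups_rarely_significant(self):
        n_sig = n_tot = 0
        for seed in range(20):
            df = self._study(np.random.default_rng(seed))
            report = disease_effect_report(
                df[df.group == "control"], df[df.group == "patient"]
            )
            n_sig += (report.p < 0.05).sum()
            n_tot += len(report)
        assert n_sig / n_tot < 0.12  # ~chance rate at alpha=0.05

    def test_large_shift_detected_with_direction(self):
        df = self._study(np.random.default_rng(3), shift=2.0)
        report = disease_effect_report(
            df[df.group == "control"], df[df.group == "patient"]
        )
        assert (report.p < 0.01).all()
        assert (report.direction == "patients_lower").all()

    def test_empty_group_rejected(self, rng):
        df = self._study(np.random.default_rng(0))
        with pytest.raises(ValueError):
            disease_effect_report(df[df.group == "control"], df.iloc[0:0])


def test_build_study_table_deltas(tiny_cohort, tiny_spec):
    records, _ = tiny_cohort
    rows = [
        {
            "subject_id": r.subject_id,
            "session": r.session,
            "density": 0.06,
            "clustering": 0.3,
        }
        for r in records
    ]
    table = build_study_table(records, rows)
    pat = table[(table.group == "patient") & (table.session == "placebo")]
    assert np.allclose(pat.delta_category_fluency, 0.0)
    drug = table[(table.group == "patient") & (table.session == "atomoxetine")]
    assert drug.delta_ssrt_ms.notna().all()
    ctrl = table[table.group == "control"]
    assert ctrl.delta_ssrt_ms.isna().all()
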