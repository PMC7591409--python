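import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from frailfalls import (
    ContingencyTable,
    FallCategory,
    FallFrailtyGroup,
    chi_square,
    classify_falls,
    cross_tabulate,
    fall_frailty_group,
    frailty_increment_or,
    logistic_or,
    odds_ratio_2x2,
    run_full_analysis,
)


class TestClassification:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (0, FallCategory.NO_FALLS),
            (1, FallCategory.ONE_FALL),
            (2, FallCategory.RECURRENT),
            (7, FallCategory.RECURRENT),
        ],
    )
    def test_falls_categories(self, n, expected):
        assert classify_falls(n) is expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            classify_falls(-1)

    @pytest.mark.parametrize(
        "cat,frail,expected",
        [
            (FallCategory.RECURRENT, True, FallFrailtyGroup.FALLER_FRAIL),
            (FallCategory.NO_FALLS, True, FallFrailtyGroup.NONFALLER_FRAIL),
            (FallCategory.ONE_FALL, False, FallFrailtyGroup.FALLER_NONFRAIL),
            (FallCategory.NO_FALLS, False, FallFrailtyGroup.NONFALLER_NONFRAIL),
        ],
    )
    def test_fall_frailty_groups(self, cat, frail, expected):
        assert fall_frailty_group(cat, frail) is expected


class TestCrossTabulate:
    def test_hand_counted_fixture(self):
        df = pd.DataFrame(
            {
                "status": ["frail", "frail", "non_frail", "non_frail", "non_frail", "frail"],
                "falls": ["recurrent", "no_falls", "no_falls", "one_fall", "no_falls", "recurrent"],
            }
        )
        tab = cross_tabulate(
            df, "status", "falls",
            row_order=["non_frail", "frail"],
            col_order=["no_falls", "one_fall", "recurrent"],
        )
        assert tab.counts.tolist() == [[2, 1, 0], [1, 0, 2]]
        assert tab.row_percentages[1].tolist() == pytest.approx([100 / 3, 0.0, 200 / 3])

    def test_missing_rows_are_counted_not_dropped_silently(self):
        df = pd.DataFrame({"a": [1, 1, np.nan], "b": ["x", "y", "x"]})
        tab = cross_tabulate(df, "a", "b")
        assert tab.n == 2 and tab.n_excluded == 1

    def test_single_category_column(self):
        df = pd.DataFrame({"a": [1, 2, 2], "b": ["x", "x", "x"]})
        tab = cross_tabulate(df, "a", "b")
        assert tab.counts.shape[1] == 1
        assert np.allclose(tab.row_percentages, 100.0)

    def test_empty_slice_rejected(self):
        with pytest.raises(ValueError):
            cross_tabulate(pd.DataFrame({"a": [], "b": []}), "a", "b")


class TestChiSquare:
    def test_proportional_table_has_zero_statistic(self):
        tab = ContingencyTable(["r1", "r2"], ["c1", "c2"], np.array([[10, 20], [20, 40]]))
        stat, dof, p = chi_square(tab)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        tab = ContingencyTable(["r1", "r2"], ["c1", "c2"], np.array([[10, 20], [20, 10]]))
        stat, dof, _ = chi_square(tab)
        assert stat == pytest.approx(20 / 3, abs=1e-9)
        assert dof == 1

    def test_degrees_of_freedom_formula(self):
        counts = np.ones((5, 4), dtype=int) * 5
        _, dof, _ = chi_square(ContingencyTable(list("abcde"), list("wxyz"), counts))
        assert dof == 12

    def test_zero_expected_count_rejected(self):
        tab = ContingencyTable(["r1", "r2"], ["c1", "c2"], np.array([[0, 5], [0, 5]]))
        with pytest.raises(ValueError, match="merge"):
            chi_square(tab)


class TestOddsRatio2x2:
    def test_symmetric_table_is_null(self):
        est = odds_ratio_2x2(1, 1, 1, 1)
        assert est.odds_ratio == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_published_baseline_recurrent_falls_table(self):
        # frail: 72 recurrent / 149 not; non-frail: 62 / 631
        est = odds_ratio_2x2(72, 149, 62, 631)
        assert est.odds_ratio == pytest.approx((72 * 631) / (149 * 62), rel=1e-12)
        assert est.odds_ratio == pytest.approx(4.918, abs=1e-3)

    def test_haldane_anscombe_correction_flagged(self):
        est = odds_ratio_2x2(0, 10, 5, 5)
        assert est.continuity_corrected
        assert est.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5), rel=1e-12)

    def test_empty_margin_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            odds_ratio_2x2(0, 0, 5, 5)

    def test_simultaneous_row_column_swap_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, size=4)
            orig = odds_ratio_2x2(a, b, c, d).odds_ratio
            swapped = odds_ratio_2x2(d, c, b, a).odds_ratio  # both axes flipped
            assert swapped == pytest.approx(orig, rel=1e-12)
            inverted = odds_ratio_2x2(c, d, a, b).odds_ratio  # exposure labels exchanged
            assert inverted == pytest.approx(1.0 / orig, rel=1e-12)


class TestLogisticOr:
    def test_binary_exposure_matches_cross_product(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 300)
        y = (rng.random(300) < np.where(x == 1, 0.4, 0.2)).astype(float)
        a = int(((x == 1) & (y == 1)).sum())
        b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum())
        d = int(((x == 0) & (y == 0)).sum())
        est = logistic_or(y, x)["exposure"]
        assert est.odds_ratio == pytest.approx(odds_ratio_2x2(a, b, c, d).odds_ratio, abs=1e-6)
        assert est.model == "logistic_unadjusted"

    def test_wald_ci_coverage_on_simulated_data(self):
        """True log-OR 1.0; the 95% Wald CI should cover it in >= 93% of replicates."""
        rng = np.random.default_rng(12)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(size=2000)
            y = (rng.random(2000) < expit(-1.0 + 1.0 * x)).astype(float)
            est = logistic_or(y, x)["exposure"]
            covered += est.ci_low <= np.e <= est.ci_high
        assert covered / n_rep >= 0.93

    def test_adjusted_model_reports_covariates(self):
        rng = np.random.default_rng(9)
        n = 500
        cov = pd.DataFrame(
            {
                "bmi": rng.normal(26, 4, n),
                "smoking": rng.choice(["never", "previous", "current"], n),
            }
        )
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < 0.3).astype(float)
        fits = logistic_or(y, x, cov, exposure_name="frail")
        assert fits["frail"].model == "logistic_adjusted"
        assert "bmi" in fits["frail"].adjusted_for
        assert "smoking_previous" in fits and "smoking_current" in fits

    def test_complete_case_exclusions_counted(self):
        y = [0, 1, 0, 1, 0, 1, 0, 1]
        x = [0, 1, 0, 1, 1, 0, np.nan, 1]
        est = logistic_or(y, x)["exposure"]
        assert est.n == 7 and est.n_excluded == 1

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_or(np.zeros(20), np.arange(20))


class TestFrailtyIncrementOr:
    def test_or_is_exponentiated_scaled_coefficient(self):
        rng = np.random.default_rng(21)
        fi = rng.beta(2, 8, 800)
        y = (rng.random(800) < expit(-2.0 + 5.0 * fi)).astype(float)
        est = frailty_increment_or(y, fi)
        raw = logistic_or(y, fi * 100, exposure_name="x")["x"]
        assert est.odds_ratio == pytest.approx(raw.odds_ratio, rel=1e-9)

    def test_recovers_generating_or_at_n1000(self):
        # per-0.01 OR of 1.05 simulated directly from the logistic model
        rng = np.random.default_rng(30)
        fi = rng.beta(2.8, 12.9, 1000)
        y = (rng.random(1000) < expit(-2.7 + np.log(1.05) * 100 * fi)).astype(float)
        est = frailty_increment_or(y, fi)
        assert 1.03 <= est.odds_ratio <= 1.07

    def test_constant_index_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            frailty_increment_or(np.tile([0, 1], 10), np.full(20, 0.2))


class TestRunFullAnalysis:
    def test_report_structure_and_ns(self, default_cohort):
        report = run_full_analysis(default_cohort)
        from frailfalls import build_index_table

        base = default_cohort.data[default_cohort.data["visit_age"] == 75].reset_index(drop=True)
        fib = build_index_table(default_cohort)
        fib = fib[fib["visit_age"] == 75].reset_index(drop=True)
        expected_n = int((base["falls_12m"].notna() & fib["index"].notna()).sum())
        assert report.analysis_ns["frailty75_falls75"] == expected_n
        assert set(report.quintile_tables) >= {"frailty75_falls75", "frailty75_falls80"}
        assert "frail75_recurrent80" in report.estimates
        # every quintile table partitions its analysis subsample
        for key, tab in report.quintile_tables.items():
            assert tab["table"].counts.sum() == report.analysis_ns[key]

    def test_generator_truth_reproduced_within_monte_carlo_tolerance(self, default_cohort):
        report = run_full_analysis(default_cohort)
        inc = report.incidence.set_index("visit_age")
        # generator truth: baseline any-fall 28.4%, recurrent 14.7%
        n = inc.loc[75, "n_valid_falls"]
        se_any = 100 * np.sqrt(0.284 * 0.716 / n)
        assert abs(inc.loc[75, "pct_any_fall"] - 28.4) < 3 * se_any
        se_rec = 100 * np.sqrt(0.147 * 0.853 / n)
        assert abs(inc.loc[75, "pct_recurrent"] - 14.7) < 3 * se_rec

    def test_empty_cohort_rejected(self, tiny_cohort):
        empty = tiny_cohort
        empty.data = empty.data.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            run_full_analysis(empty)

    def test_json_report_written(self, default_cohort, tmp_path):
        report = run_full_analysis(default_cohort)
        out = tmp_path / "report.json"
        report.to_json(out)
        import json

        payload = json.loads(out.read_text())
        assert "estimates" in payload and "quintile_tables" in payload
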