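"""Metrics, confidence intervals, lead times, rank test, alert burden."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from wardalert.episodes import ContingencyTable, WarningPeriod
from wardalert.evaluation import (
    DegenerateVarianceError,
    UndefinedMetricError,
    alerting_fraction,
    contingency_metrics,
    group_burden_comparison,
    lead_time_summary,
    mann_whitney,
    prelude_bins,
    proportion_ci,
)
from wardalert.scoring import ScoreSeries

from conftest import make_admission
from oracles import exact_mw_p, quartiles_sorted


def series_from(t, score, threshold=3.0, valid=None, scenario="continuous"):
    t = np.asarray(t)
    score = np.asarray(score, dtype=float)
    valid = np.ones(len(t), dtype=bool) if valid is None else np.asarray(valid)
    return ScoreSeries(scenario, threshold,
                       pd.DataFrame({"t_min": t, "score": score, "valid": valid}))


class TestContingencyMetrics:
    def test_symmetric_table_has_half_sensitivity_and_specificity(self):
        m = contingency_metrics(ContingencyTable(10, 40, 40, 10, patient_days=100.0))
        assert m.sensitivity.value == 0.5 == m.specificity.value

    def test_nne_is_reciprocal_ppv(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp = int(rng.integers(1, 200)), int(rng.integers(0, 5000))
            tn, fn = int(rng.integers(1, 5000)), int(rng.integers(0, 200))
            m = contingency_metrics(ContingencyTable(tp, fp, tn, fn, patient_days=100.0))
            assert m.nne.value * m.ppv.value == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("table,metric", [
        (ContingencyTable(0, 0, 10, 0, 1.0), "sensitivity"),
        (ContingencyTable(0, 0, 10, 5, 1.0), "ppv"),
        (ContingencyTable(5, 0, 0, 0, 1.0), "specificity"),
        (ContingencyTable(0, 5, 10, 5, 1.0), "nne"),
    ])
    def test_zero_denominators_name_the_metric(self, table, metric):
        with pytest.raises(UndefinedMetricError, match=metric):
            contingency_metrics(table)


class TestProportionCI:
    def test_degenerate_and_error_cases(self):
        assert proportion_ci(0, 50) == (0.0, 0.0)
        assert proportion_ci(50, 50) == (1.0, 1.0)
        with pytest.raises(UndefinedMetricError):
            proportion_ci(0, 0)

    def test_matches_statsmodels_normal_interval(self):
        from statsmodels.stats.proportion import proportion_confint
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(1, 5000))
            k = int(rng.integers(0, n + 1))
            lo, hi = proportion_ci(k, n)
            ref_lo, ref_hi = proportion_confint(k, n, alpha=0.05, method="normal")
            assert lo == pytest.approx(max(0.0, ref_lo), abs=1e-9)
            assert hi == pytest.approx(min(1.0, ref_hi), abs=1e-9)


class TestLeadTime:
    def test_single_true_positive_lead(self):
        p = WarningPeriod(0, 300, [0], truncated_by_eoc=True, classification="TP", eoc_t=300)
        s = lead_time_summary([p], n_eoc=1)
        assert s.leads_h == [5.0]
        assert s.median_h == 5.0
        assert s.plateau_pct == 100.0

    def test_no_true_positives_gives_flat_zero_curve(self):
        s = lead_time_summary([], n_eoc=4)
        assert s.median_h is None and s.iqr_h is None
        assert (s.curve["cum_pct_detected"] == 0).all()

    def test_curve_monotone_plateau_equals_sensitivity(self):
        rng = np.random.default_rng(8)
        n_eoc = 40
        periods = []
        for i in range(25):
            start = int(rng.integers(0, 2000))
            eoc = start + int(rng.integers(1, 4000))
            periods.append(WarningPeriod(start, eoc, [start], True, "TP", eoc))
        s = lead_time_summary(periods, n_eoc=n_eoc)
        diffs = np.diff(s.curve["cum_pct_detected"].to_numpy())
        assert (diffs >= 0).all()
        assert s.plateau_pct == pytest.approx(100.0 * 25 / n_eoc)

    def test_median_iqr_match_sort_oracle(self):
        rng = np.random.default_rng(21)
        for n in (1, 2, 3, 7, 30):
            leads_min = rng.integers(10, 5000, size=n)
            periods = [WarningPeriod(0, int(t), [0], True, "TP", int(t)) for t in leads_min]
            s = lead_time_summary(periods, n_eoc=n)
            q1, med, q3 = quartiles_sorted([t / 60.0 for t in leads_min])
            assert s.median_h == pytest.approx(med)
            assert s.iqr_h == (pytest.approx(q1), pytest.approx(q3))


class TestMannWhitney:
    def test_identical_samples_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, z, p = mann_whitney(x, x)
        assert u == len(x) ** 2 / 2.0
        assert z == 0.0 and p == 1.0

    def test_complete_separation_is_extreme(self):
        u, z, p = mann_whitney([10.0, 11.0, 12.0, 13.0, 14.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert u == 25.0  # mx * my
        assert z > 2.5 and p == pytest.approx(2 / 252)  # both extreme assignments

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 12).round(1)  # rounding forces ties
        y = rng.normal(0.5, 1, 9).round(1)
        u_xy, z_xy, p_xy = mann_whitney(x, y)
        u_yx, z_yx, p_yx = mann_whitney(y, x)
        assert z_xy == pytest.approx(-z_yx)
        assert p_xy == pytest.approx(p_yx)
        assert u_xy + u_yx == len(x) * len(y)

    def test_matches_scipy_asymptotic_at_large_n(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            x = rng.normal(0, 1, int(rng.integers(9, 30))).round(1)
            y = rng.normal(0.3, 1.2, int(rng.integers(9, 30))).round(1)
            u, z, p = mann_whitney(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_close_to_exact_permutation_p_at_small_n(self):
        rng = np.random.default_rng(9)
        for _ in range(8):
            m, n = int(rng.integers(3, 9)), int(rng.integers(3, 9))
            x = rng.normal(0, 1, m).round(1)
            y = rng.normal(0.8, 1, n).round(1)
            _, _, p = mann_whitney(x, y)
            assert abs(p - exact_mw_p(list(x), list(y))) <= 0.02

    def test_constant_pooled_sample_degenerates(self):
        with pytest.raises(DegenerateVarianceError):
            mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])


class TestAlertBurden:
    def test_extreme_fractions(self):
        a = make_admission(los_min=2880)
        always = series_from(np.arange(100), np.full(100, 4.0))
        assert alerting_fraction(always, a, 0, 100) == 1.0
        never = series_from(np.arange(100), np.full(100, 1.0))
        assert alerting_fraction(never, a, 0, 100) == 0.0
        assert alerting_fraction(never, a, 500, 600) is None  # no scored minutes

    def test_fraction_matches_minute_sweep(self):
        rng = np.random.default_rng(11)
        t = np.sort(rng.choice(3000, 700, replace=False))
        score = rng.uniform(0, 5, 700)
        valid = rng.random(700) > 0.2
        s = series_from(t, score, valid=valid)
        a = make_admission(los_min=3000)
        for ws, we in [(0, 3000), (100, 700), (2000, 2500)]:
            num = den = 0
            for ti, sc, va in zip(t, score, valid):
                if ws <= ti < we and va:
                    den += 1
                    num += sc >= 3.0
            expected = num / den if den else None
            assert alerting_fraction(s, a, ws, we) == expected

    def test_prelude_bins_uniform_rate_and_late_alerts(self):
        a = make_admission(los_min=8000)
        t = np.arange(0, 4320)
        eoc_t = 4320
        # uniform alerting: every 4th minute alerts
        score = np.where(t % 4 == 0, 4.0, 0.0)
        bins = prelude_bins(series_from(t, score), a, eoc_t)
        assert all(b == pytest.approx(0.25) for b in bins)
        # alerts only in the final 24 h
        late = np.where(t >= eoc_t - 1440, 4.0, 0.0)
        b1, b2, b3 = prelude_bins(series_from(t, late), a, eoc_t)
        assert (b1, b2) == (0.0, 0.0) and b3 == 1.0

    def test_prelude_bins_clip_before_admission(self):
        a = make_admission(los_min=8000)
        t = np.arange(0, 1500)
        s = series_from(t, np.full(len(t), 4.0))
        b1, b2, b3 = prelude_bins(s, a, eoc_t=1500)  # only 25 h of stay
        assert b1 is None  # bin entirely before admission
        assert b2 == 1.0 and b3 == 1.0

    def test_group_comparison_sign_medians_and_exclusions(self):
        rng = np.random.default_rng(12)
        non_eoc = list(rng.beta(1, 30, 150)) + [None, None]
        eoc = list(rng.beta(2, 10, 40)) + [None]
        cmp = group_burden_comparison(non_eoc, eoc)
        assert cmp.n == (150, 40) and cmp.n_excluded == (2, 1)
        assert cmp.z < 0  # escalation group stochastically larger
        q1, med, q3 = quartiles_sorted([v for v in non_eoc if v is not None])
        assert cmp.median[0] == pytest.approx(med)
        assert cmp.iqr[0] == (pytest.approx(q1), pytest.approx(q3))
        same = list(rng.beta(1, 10, 50))
        sym = group_burden_comparison(same, same)
        assert sym.p == 1.0
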