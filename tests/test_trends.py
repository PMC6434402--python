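import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patx import (
    DayProfile,
    check_compliance_balance,
    classify_trend,
    extract_trends,
    mann_kendall,
    monthly_panel,
    seasonal_decompose_additive,
)
from patx.trends import MonthlyPanel, TrendResult

from oracles import mk_brute


class TestMonthlyPanel:
    def _profiles(self, calendar, spec):
        """spec: list of (date, compliant, target_minutes)."""
        return [
            DayProfile("s1", d, 1440 if c else 900, c, target_minutes=t)
            for d, c, t in spec
        ]

    def test_normalizes_by_compliant_days(self, calendar):
        sept = dt.date(2015, 9, 1)
        profs = self._profiles(
            calendar,
            [
                (sept, True, 10),
                (sept + dt.timedelta(days=1), True, 20),
                (sept + dt.timedelta(days=2), True, 30),
            ],
        )
        panel = monthly_panel(profs, calendar)
        i = calendar.month_index(2015, 9)
        assert panel.normalized[i] == pytest.approx(20.0)
        assert panel.compliant_days[i] == 3

    def test_noncompliant_days_excluded_entirely(self, calendar):
        sept = dt.date(2015, 9, 1)
        profs = self._profiles(
            calendar,
            [(sept, True, 45), (sept + dt.timedelta(days=1), False, 500)],
        )
        panel = monthly_panel(profs, calendar)
        i = calendar.month_index(2015, 9)
        assert panel.normalized[i] == 45.0
        assert panel.compliant_days[i] == 1

    def test_month_with_no_compliant_days_is_missing(self, calendar):
        panel = monthly_panel(
            self._profiles(calendar, [(dt.date(2015, 9, 1), False, 0)]), calendar
        )
        assert np.isnan(panel.normalized[calendar.month_index(2015, 9)])

    def test_days_in_breaks_ignored(self, calendar):
        panel = monthly_panel(
            self._profiles(calendar, [(dt.date(2016, 6, 15), True, 60)]), calendar
        )
        assert panel.target_sum.sum() == 0


class TestSeasonalDecomposition:
    def test_pure_periodic_series_gives_constant_trend(self):
        rng = np.random.default_rng(3)
        pattern = rng.uniform(0, 40, 9)
        series = np.tile(pattern, 2)
        d = seasonal_decompose_additive(series, period=9)
        defined = ~np.isnan(d.trend)
        assert defined.sum() == 10
        assert np.allclose(d.trend[defined], pattern.mean(), rtol=1e-9)
        expect_seasonal = pattern - pattern.mean()
        assert np.allclose(d.seasonal[:9], expect_seasonal, rtol=1e-9, atol=1e-9)

    def test_linear_series_trend_exact_and_seasonal_zero(self):
        t = np.arange(18)
        series = 5.0 + 1.25 * t
        d = seasonal_decompose_additive(series, period=9)
        defined = ~np.isnan(d.trend)
        assert np.allclose(d.trend[defined], series[defined], rtol=1e-9)
        assert np.allclose(d.seasonal, 0.0, atol=1e-9)

    def test_constant_series(self):
        d = seasonal_decompose_additive(np.full(18, 7.0), period=9)
        defined = ~np.isnan(d.trend)
        assert np.allclose(d.trend[defined], 7.0)
        assert np.allclose(d.seasonal, 0.0, atol=1e-12)
        assert np.allclose(d.remainder[defined], 0.0, atol=1e-12)

    def test_additive_identity_and_seasonal_centering(self):
        rng = np.random.default_rng(9)
        series = 30 + 0.8 * np.arange(27) + rng.normal(0, 4, 27)
        d = seasonal_decompose_additive(series, period=9)
        defined = ~np.isnan(d.trend)
        recon = d.trend[defined] + d.seasonal[defined] + d.remainder[defined]
        assert np.allclose(recon, series[defined], rtol=1e-9)
        assert abs(d.seasonal[:9].sum()) < 1e-9

    def test_matches_statsmodels_reference(self):
        """Independent cross-check of the classical decomposition."""
        sm = pytest.importorskip("statsmodels.tsa.seasonal")
        rng = np.random.default_rng(17)
        series = 25 + 0.5 * np.arange(18) + rng.normal(0, 3, 18)
        ours = seasonal_decompose_additive(series, period=9)
        ref = sm.seasonal_decompose(series, model="additive", period=9)
        assert np.allclose(ours.trend, ref.trend, equal_nan=True, atol=1e-8)
        assert np.allclose(ours.seasonal, ref.seasonal, atol=1e-8)

    def test_interior_missing_interpolated_and_flagged(self):
        series = 10.0 + np.arange(18)
        series[7] = np.nan
        d = seasonal_decompose_additive(series, period=9)
        assert d.interpolated[7]
        defined = ~np.isnan(d.trend)
        assert np.allclose(d.trend[defined], (10.0 + np.arange(18))[defined], rtol=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="needs"):
            seasonal_decompose_additive(np.arange(17.0), period=9)


class TestMannKendall:
    def test_exhaustive_agreement_with_brute_force(self):
        """All sequences of length 3..7 over {0,1,2}: exact S and Var,
        p within 1e-12 of the pairwise oracle (heavy ties included)."""
        for n in range(3, 8):
            for combo in itertools.product([0.0, 1.0, 2.0], repeat=n):
                s, var, z, p = mann_kendall(np.array(combo))
                bs, bvar, bz, bp = mk_brute(list(combo))
                assert s == bs
                assert var == pytest.approx(bvar, abs=1e-12)
                assert z == pytest.approx(bz, abs=1e-12)
                assert p == pytest.approx(bp, abs=1e-12)

    @pytest.mark.parametrize(
        "series, expected_s",
        [([1, 2, 3], 3), ([5, 5, 5, 5], 0), ([3, 1, 2], -1)],
    )
    def test_worked_examples(self, series, expected_s):
        s, var, z, p = mann_kendall(series)
        assert s == expected_s
        if expected_s == 0:
            assert z == 0.0 and p == pytest.approx(1.0)

    def test_nan_positions_dropped_in_order(self):
        s1, *_ = mann_kendall([1, np.nan, 2, 3, np.nan, 4])
        s2, *_ = mann_kendall([1, 2, 3, 4])
        assert s1 == s2

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall([1.0, 2.0])

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=3,
            max_size=20,
            unique=True,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_under_reversal(self, xs):
        s, var, z, p = mann_kendall(xs)
        rs, rvar, rz, rp = mann_kendall(xs[::-1])
        assert rs == -s
        assert rvar == pytest.approx(var)
        assert rz == pytest.approx(-z)
        assert rp == pytest.approx(p)

    def test_agrees_with_scipy_kendalltau_s_on_tie_free_data(self):
        from scipy.stats import kendalltau

        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.permutation(12).astype(float)
            s, *_ = mann_kendall(x)
            tau = kendalltau(np.arange(12), x).statistic
            assert s == round(tau * (12 * 11 / 2))


class TestClassifyTrend:
    @pytest.mark.parametrize(
        "p, s, expected",
        [
            (0.01, 40, "positive"),
            (0.01, -40, "negative"),
            (0.30, 5, "none"),
            (0.049, 0, "none"),
        ],
    )
    def test_labeling(self, p, s, expected):
        assert classify_trend(s, p) == expected

    @given(
        st.lists(
            st.floats(min_value=0.1, max_value=100, allow_nan=False),
            min_size=18,
            max_size=18,
            unique=True,
        ),
        st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_sign_flip(self, xs, c):
        s, _, _, p = mann_kendall(xs)
        base = classify_trend(s, p)
        s2, _, _, p2 = mann_kendall([c * v for v in xs])
        assert classify_trend(s2, p2) == base
        s3, _, _, p3 = mann_kendall([-v for v in xs])
        flipped = classify_trend(s3, p3)
        swap = {"positive": "negative", "negative": "positive", "none": "none"}
        assert flipped == swap[base]


def _panel(sid, normalized, compliant_days=None, months=None):
    n = len(normalized)
    months = months or [(2015, 8 + i) if i < 5 else (2016, i - 4) for i in range(n)]
    return MonthlyPanel(
        subject_id=sid,
        months=months,
        target_sum=np.asarray(normalized, dtype=float),
        compliant_days=np.asarray(compliant_days if compliant_days is not None else [25] * n),
        normalized=np.asarray(normalized, dtype=float),
    )


class TestExtractTrends:
    def test_strong_monotone_increase_is_positive(self, calendar):
        series = 5 + 3.0 * np.arange(18)
        (res,) = extract_trends([_panel("up", series, months=calendar.months)], period=9)
        assert res.label == "positive"
        assert res.n_used == 10

    def test_strong_decrease_is_negative(self, calendar):
        series = 60 - 3.0 * np.arange(18)
        (res,) = extract_trends([_panel("dn", series, months=calendar.months)], period=9)
        assert res.label == "negative"

    def test_constant_subject_is_none(self, calendar):
        (res,) = extract_trends(
            [_panel("flat", np.full(18, 20.0), months=calendar.months)], period=9
        )
        assert res.label == "none"

    def test_too_short_series_labeled_none_with_warning(self, calendar, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="patx.trends"):
            (res,) = extract_trends(
                [_panel("short", np.arange(5.0), months=calendar.months[:5])], period=9
            )
        assert res.label == "none"
        assert any("short" in r.message for r in caplog.records)


class TestComplianceBalance:
    def _results(self, labels):
        return [
            TrendResult(sid, 1 if l == "positive" else -1, 1, 0, 0.01, l)
            for sid, l in labels.items()
        ]

    def test_identical_distributions_not_significant(self):
        days = [20, 22, 24, 26] * 4
        panels = [
            _panel(s, np.ones(16), compliant_days=days, months=[(2015, 8)] * 16)
            for s in ("a", "b", "c")
        ]
        results = self._results({"a": "positive", "b": "negative", "c": "none"})
        h, p = check_compliance_balance(panels, results)
        assert p > 0.99

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(0)
        base = rng.integers(18, 28, 18).tolist()
        shifted = (rng.integers(2, 8, 18)).tolist()
        panels = [
            _panel("a", np.ones(18), compliant_days=base),
            _panel("b", np.ones(18), compliant_days=base),
            _panel("c", np.ones(18), compliant_days=shifted),
        ]
        results = self._results({"a": "positive", "b": "negative", "c": "none"})
        h, p = check_compliance_balance(panels, results)
        assert p < 0.05

    def test_null_rejection_rate_near_alpha(self):
        """Three groups from one distribution: ~5% rejections at alpha .05."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            panels, labels = [], {}
            for sid, lbl in zip("abc", ("positive", "negative", "none")):
                days = rng.integers(15, 30, 18).tolist()
                panels.append(_panel(sid, np.ones(18), compliant_days=days))
                labels[sid] = lbl
            _, p = check_compliance_balance(panels, self._results(labels))
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)

    def test_single_group_rejected(self):
        panels = [_panel("a", np.ones(18))]
        results = self._results({"a": "positive"})
        with pytest.raises(ValueError):
            check_compliance_balance(panels, results)
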