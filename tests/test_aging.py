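import numpy as np
import pandas as pd
import pytest

from metaboclock import (
    age_acceleration,
    chi_squared_test,
    classify_acceleration,
    compare_characteristics,
    fit_age_spline,
    welch_t,
    welch_t_from_summary,
)
from metaboclock.aging import ACCELERATED, DECELERATED, INTERMEDIATE


class TestAgeSpline:
    def test_linear_data_reproduced(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(45, 80, 120)
        y = 0.9 * x + 5.0
        sp = fit_age_spline(x, y)
        np.testing.assert_allclose(sp.fitted, y, atol=1e-6)
        # linear extrapolation continues the line
        assert sp(30.0) == pytest.approx(0.9 * 30 + 5, abs=1e-5)
        assert sp(95.0) == pytest.approx(0.9 * 95 + 5, abs=1e-5)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(45, 80, 300)
        y = 50 + 0.3 * x + rng.normal(0, 3, 300)
        sp = fit_age_spline(x, y)
        assert abs((y - sp.fitted).sum()) < 1e-6 * len(x)

    def test_noisy_quadratic_tracks_true_curve(self):
        """Simulation oracle: on a noisy quadratic the GCV spline stays
        within 3 noise sd of the true curve on an interior grid."""
        rng = np.random.default_rng(42)
        x = rng.uniform(45, 80, 500)
        true = lambda t: 30 + 0.002 * (t - 45) ** 2 + 0.5 * t
        y = true(x) + rng.normal(0, 1.0, 500)
        sp = fit_age_spline(x, y)
        grid = np.linspace(50, 75, 60)
        assert np.max(np.abs(sp(grid) - true(grid))) < 3.0

    def test_duplicate_ages_handled(self):
        x = np.repeat(np.arange(45, 70, 1.0), 4)
        rng = np.random.default_rng(2)
        y = x + rng.normal(0, 1, x.size)
        sp = fit_age_spline(x, y)
        assert np.isfinite(sp.fitted).all()

    def test_input_validation(self):
        with pytest.raises(ValueError, match="20"):
            fit_age_spline(np.arange(10.0), np.arange(10.0))
        x = np.array([50.0, 60.0, 70.0] * 10)
        with pytest.raises(ValueError, match="distinct"):
            fit_age_spline(x, x)


class TestClassifyAcceleration:
    def _records(self, deltas):
        return pd.DataFrame({"delta": deltas},
                            index=[f"s{i}" for i in range(len(deltas))])

    @pytest.mark.parametrize("delta,expected", [
        (8.0, ACCELERATED),
        (-8.0, DECELERATED),
        (7.0, INTERMEDIATE),    # strict inequality at the boundary
        (-7.0, INTERMEDIATE),
        (0.0, INTERMEDIATE),
    ])
    def test_strict_threshold(self, delta, expected):
        out = classify_acceleration(self._records([delta]), threshold=7.0)
        assert out["accel_class"].iloc[0] == expected

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        rec = self._records(rng.normal(0, 10, 200))
        prev_extreme = None
        for thr in (5.0, 7.0, 10.0, 15.0):
            out = classify_acceleration(rec, threshold=thr)
            extreme = set(out.index[out["accel_class"] != INTERMEDIATE])
            if prev_extreme is not None:
                assert extreme <= prev_extreme
            prev_extreme = extreme

    def test_quantile_tails(self):
        rng = np.random.default_rng(4)
        rec = self._records(rng.normal(0, 5, 1000))
        out = classify_acceleration(rec, tail_fraction=0.10)
        counts = out["accel_class"].value_counts()
        assert counts[ACCELERATED] == pytest.approx(100, abs=2)
        assert counts[DECELERATED] == pytest.approx(100, abs=2)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            classify_acceleration(self._records([1.0]), threshold=0.0)


class TestWelch:
    def test_closed_form_example(self):
        res = welch_t_from_summary(1.0, 1.0, 10, 0.0, 1.0, 10)
        assert res.statistic == pytest.approx(2.236, abs=1e-3)
        assert res.df == pytest.approx(18.0)
        assert res.p == pytest.approx(0.038, abs=1e-3)

    def test_identical_groups(self):
        res = welch_t_from_summary(5.0, 2.0, 30, 5.0, 2.0, 30)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_raw_equals_summary_path(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 2, 25)
        raw = welch_t(x, y)
        summ = welch_t_from_summary(x.mean(), x.std(ddof=1), x.size,
                                    y.mean(), y.std(ddof=1), y.size)
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.df == pytest.approx(summ.df, abs=1e-12)
        assert raw.p == pytest.approx(summ.p, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="standard deviation"):
            welch_t_from_summary(1.0, 0.0, 10, 2.0, 0.0, 10)
        with pytest.raises(ValueError, match="n >= 2"):
            welch_t_from_summary(1.0, 1.0, 1, 2.0, 1.0, 10)


class TestChiSquared:
    def test_closed_form_uncorrected(self):
        res = chi_squared_test([[20, 10], [10, 20]], yates=False)
        assert res.statistic == pytest.approx(20 / 3, abs=1e-9)
        assert res.df == 1
        assert res.p == pytest.approx(0.00982, abs=1e-4)

    def test_uniform_table_null(self):
        res = chi_squared_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_yates_default_on_for_2x2(self):
        t = [[20, 10], [10, 20]]
        assert chi_squared_test(t).statistic < chi_squared_test(t, yates=False).statistic

    def test_low_expected_count_warns(self):
        with pytest.warns(UserWarning, match="expected count"):
            chi_squared_test([[2, 3], [3, 2]], yates=False)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared_test([[0, 0], [5, 3]])

    def test_agrees_with_permutation_oracle(self):
        """Uncorrected 2x2 chi-squared p is consistent with a brute-force
        permutation null on small tables: because the permutation statistic
        is discrete, the asymptotic p must fall inside the bracket between
        the strict (>) and non-strict (>=) permutation tails, up to
        Monte-Carlo error."""
        import warnings
        rng = np.random.default_rng(6)
        n_perm = 4000
        for table in ([[12, 5], [6, 13]], [[8, 9], [10, 7]], [[15, 2], [5, 12]]):
            table = np.array(table)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = chi_squared_test(table, yates=False)
            n1, n2 = table.sum(axis=1)
            c1 = table[:, 0].sum()
            pool = np.r_[np.repeat(1, c1), np.repeat(0, table[:, 1].sum())]
            n_gt = n_ge = 0
            for _ in range(n_perm):
                rng.shuffle(pool)
                a = int(pool[:n1].sum())
                t = np.array([[a, n1 - a], [c1 - a, n2 - (c1 - a)]])
                if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all():
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        stat = chi_squared_test(t, yates=False).statistic
                else:
                    stat = 0.0
                n_gt += stat > res.statistic + 1e-9
                n_ge += stat >= res.statistic - 1e-9
            mc = 3 * np.sqrt(0.25 / n_perm)
            assert n_gt / n_perm - mc <= res.p <= n_ge / n_perm + mc


class TestCompareCharacteristics:
    def _synthetic_groups(self, shift=0.0, seed=7):
        rng = np.random.default_rng(seed)
        n = 120
        meta = pd.DataFrame({
            "age_actual": rng.normal(65 + shift, 8, n),
            "sex": rng.choice(["male", "female"], n),
        }, index=[f"s{i}" for i in range(n)])
        classes = pd.Series([ACCELERATED] * (n // 2) + [DECELERATED] * (n // 2),
                            index=meta.index)
        return meta, classes

    def test_identical_groups_yield_large_p(self):
        rng = np.random.default_rng(8)
        half = pd.DataFrame({
            "age_actual": rng.normal(65, 8, 50),
            "sex": rng.choice(["male", "female"], 50),
        }, index=[f"a{i}" for i in range(50)])
        mirror = half.copy()
        mirror.index = [f"b{i}" for i in range(50)]
        meta = pd.concat([half, mirror])
        classes = pd.Series([ACCELERATED] * 50 + [DECELERATED] * 50,
                            index=meta.index)
        tab = compare_characteristics(meta, classes,
                                      {"age_actual": "continuous",
                                       "sex": "categorical"})
        assert (tab["p"] > 0.99).all()

    def test_row_matches_direct_test_call(self):
        meta, classes = self._synthetic_groups()
        tab = compare_characteristics(meta, classes,
                                      {"age_actual": "continuous"})
        direct = welch_t(meta.loc[classes == ACCELERATED, "age_actual"],
                         meta.loc[classes == DECELERATED, "age_actual"])
        assert tab.loc[0, "p"] == pytest.approx(direct.p, abs=1e-12)

    def test_missing_characteristic_errors(self):
        meta, classes = self._synthetic_groups()
        with pytest.raises(KeyError, match="height"):
            compare_characteristics(meta, classes, {"height": "continuous"})

    def test_missing_values_recorded(self):
        meta, classes = self._synthetic_groups()
        meta.loc[meta.index[:5], "age_actual"] = np.nan
        tab = compare_characteristics(meta, classes,
                                      {"age_actual": "continuous"})
        assert tab.loc[0, "n_missing"] == 5


class TestAgeAccelerationEndToEnd:
    def test_planted_fast_agers_enriched_in_accelerated(self):
        """Subjects whose latent offset exceeds +10 y must be called
        accelerated far more often than those below -10 y and vice versa."""
        rng = np.random.default_rng(9)
        n = 800
        age = rng.uniform(45, 80, n)
        delta = rng.normal(0, 10, n)
        # metabolomic age = spline-free linear trend + latent offset + score noise
        pred = 10 + 0.8 * age + delta + rng.normal(0, 2, n)
        rec = age_acceleration([f"s{i}" for i in range(n)], age, pred,
                               threshold=7.0)
        fast = rec[delta > 10]["accel_class"]
        slow = rec[delta < -10]["accel_class"]
        assert (fast == ACCELERATED).mean() > 0.8
        assert (slow == ACCELERATED).mean() < 0.05
        assert (slow == DECELERATED).mean() > 0.8

    def test_no_latent_signal_gives_symmetric_small_tails(self):
        rng = np.random.default_rng(10)
        n = 2000
        age = rng.uniform(45, 80, n)
        pred = 10 + 0.8 * age + rng.normal(0, 4, n)  # score noise only
        rec = age_acceleration([f"s{i}" for i in range(n)], age, pred,
                               threshold=7.0)
        counts = rec["accel_class"].value_counts()
        # P(|N(0,4)| > 7) ~ 8% total; each tail ~4%
        for cls in (ACCELERATED, DECELERATED):
            assert counts.get(cls, 0) / n < 0.08
        assert counts.get(ACCELERATED, 0) / n > 0.005
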