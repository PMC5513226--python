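import numpy as np
import pandas as pd
import pytest

from nestmove.inference import (
    LogisticFit,
    SeparationError,
    fit_intersection_model,
    predict_probability,
    welch_t,
    window_odds_ratio,
)
from nestmove.tracks_io import ValidationError


def records_from(days, flags, bird="b1"):
    return pd.DataFrame(
        {"bird_id": bird, "day_before_laying": days, "fixed_100m": flags}
    )


def simulate_records(rng, n, b0, b1, days=(1, 45)):
    day = rng.integers(days[0], days[1] + 1, n)
    p = 1.0 / (1.0 + np.exp(-(b0 + b1 * day)))
    return records_from(day, (rng.random(n) < p).astype(int))


def grid_search_mle(days, flags, span=6.0, iters=12, grid=41):
    """Independent nested-grid maximiser of the logistic log-likelihood."""
    day = np.asarray(days, float)
    y = np.asarray(flags, float)

    def nll(b0, b1):
        eta = b0 + b1 * day
        return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

    c0, c1, half = 0.0, 0.0, span
    for _ in range(iters):
        b0s = np.linspace(c0 - half, c0 + half, grid)
        b1s = np.linspace(c1 - half / 10, c1 + half / 10, grid)
        vals = np.array([[nll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        c0, c1 = b0s[i], b1s[j]
        half *= 0.25
    return c0, c1


class TestLogisticFit:
    def test_recovers_simulation_truth_in_wald_ci(self):
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            rec = simulate_records(rng, 5000, b0=1.0, b1=-0.08)
            f = fit_intersection_model(rec, "fixed_100m")
            ok0 = abs(f.intercept - 1.0) <= 1.96 * f.se_intercept
            ok1 = abs(f.slope + 0.08) <= 1.96 * f.se_slope
            hits += ok0 and ok1
        assert hits >= 88  # joint coverage of two ~95% intervals

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        rec = simulate_records(rng, 200, b0=0.5, b1=-0.05)
        f = fit_intersection_model(rec, "fixed_100m")
        b0, b1 = grid_search_mle(rec["day_before_laying"], rec["fixed_100m"])
        assert f.intercept == pytest.approx(b0, abs=1e-3)
        assert f.slope == pytest.approx(b1, abs=1e-3)

    def test_score_vanishes_at_mle(self):
        rng = np.random.default_rng(6)
        rec = simulate_records(rng, 1000, b0=0.0, b1=-0.03)
        f = fit_intersection_model(rec, "fixed_100m")
        assert f.score_norm < 1e-6

    def test_two_day_design_matches_closed_form_log_odds(self):
        rng = np.random.default_rng(7)
        n = 4000
        day = np.repeat([1, 45], n // 2)
        p = np.where(day == 1, 0.8, 0.2)
        flags = (rng.random(n) < p).astype(int)
        rec = records_from(day, flags)
        f = fit_intersection_model(rec, "fixed_100m")
        p1 = flags[day == 1].mean()
        p45 = flags[day == 45].mean()
        log_or = np.log(p1 / (1 - p1)) - np.log(p45 / (1 - p45))
        assert f.slope * (1 - 45) == pytest.approx(log_or, abs=1e-6)

    def test_null_slope_ci_covers_zero(self):
        rng = np.random.default_rng(8)
        day = rng.integers(1, 46, 2000)
        flags = rng.integers(0, 2, 2000)
        f = fit_intersection_model(records_from(day, flags), "fixed_100m")
        lo, hi = f.slope_ci()
        assert lo <= 0 <= hi

    def test_constant_outcome_errors(self):
        rec = records_from([1, 2, 3], [1, 1, 1])
        with pytest.raises(SeparationError, match="constant"):
            fit_intersection_model(rec, "fixed_100m")

    def test_complete_separation_errors(self):
        day = np.arange(1, 41)
        flags = (day <= 20).astype(int)
        with pytest.raises(SeparationError):
            fit_intersection_model(records_from(day, flags), "fixed_100m")

    def test_cluster_robust_widens_df(self):
        rng = np.random.default_rng(9)
        rec = pd.concat(
            [
                simulate_records(rng, 500, 0.0, -0.02).assign(bird_id=f"b{i}")
                for i in range(10)
            ],
            ignore_index=True,
        )
        f = fit_intersection_model(rec, "fixed_100m", cluster_robust=True)
        assert f.n_clusters == 10
        lo, hi = f.slope_ci()
        assert lo < f.slope < hi


class TestPredictProbability:
    def test_zero_coefficients_give_half(self):
        f = LogisticFit("r", 0.0, 0.0, 1, 1, 1, 1, 10, True, 0.0)
        assert predict_probability(f, 17) == 0.5

    def test_negative_slope_monotone(self):
        f = LogisticFit("r", 0.2, -0.05, 1, 1, 1, 1, 10, True, 0.0)
        assert predict_probability(f, 1) > predict_probability(f, 45)

    def test_closed_form_value(self):
        f = LogisticFit("r", -1.1, -0.09, 1, 1, 1, 1, 10, True, 0.0)
        assert predict_probability(f, 1) == pytest.approx(
            1.0 / (1.0 + np.exp(1.19)), abs=1e-12
        )


class TestWindowOddsRatio:
    @staticmethod
    def records_with_counts(a, b, c, d):
        rows = (
            [(3, 1)] * a + [(3, 0)] * b + [(10, 1)] * c + [(10, 0)] * d
        )
        days, flags = zip(*rows)
        return records_from(list(days), list(flags))

    def test_direct_formula_evaluation(self):
        rec = self.records_with_counts(10, 190, 5, 295)
        res = window_odds_ratio(rec, "fixed_100m", (1, 5), (6, 15))
        assert res.odds_ratio == pytest.approx((10 * 295) / (190 * 5), abs=1e-9)
        assert res.odds_ratio == pytest.approx(3.105, abs=0.001)
        se = np.sqrt(1 / 10 + 1 / 190 + 1 / 5 + 1 / 295)
        assert res.ci_low == pytest.approx(np.exp(np.log(3.10526) - 1.96 * se), rel=1e-4)
        assert res.ci_high == pytest.approx(np.exp(np.log(3.10526) + 1.96 * se), rel=1e-4)
        assert not res.corrected

    def test_equal_proportions_give_unit_odds(self):
        rec = self.records_with_counts(10, 90, 20, 180)
        res = window_odds_ratio(rec, "fixed_100m", (1, 5), (6, 15))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_cell_triggers_correction(self):
        rec = self.records_with_counts(0, 190, 5, 295)
        res = window_odds_ratio(rec, "fixed_100m", (1, 5), (6, 15))
        assert res.corrected
        assert (res.a, res.b, res.c, res.d) == (0.5, 190.5, 5.5, 295.5)

    def test_empty_window_errors(self):
        rec = self.records_with_counts(5, 5, 5, 5)
        with pytest.raises(ValidationError, match="window"):
            window_odds_ratio(rec, "fixed_100m", (20, 45), (1, 5))

    def test_equals_exponentiated_window_indicator_logit(self):
        rng = np.random.default_rng(11)
        rec = self.records_with_counts(14, 186, 9, 291)
        res = window_odds_ratio(rec, "fixed_100m", (1, 5), (6, 15))
        # independent check: logistic fit on the window indicator
        import statsmodels.api as sm

        day = rec["day_before_laying"]
        ind = ((day >= 1) & (day <= 5)).astype(float)
        fit = sm.Logit(rec["fixed_100m"], sm.add_constant(ind)).fit(disp=0)
        assert res.odds_ratio == pytest.approx(np.exp(fit.params.iloc[1]), abs=1e-6)

    def test_ci_contains_or(self):
        rec = self.records_with_counts(7, 193, 12, 288)
        res = window_odds_ratio(rec, "fixed_100m", (1, 5), (6, 15))
        assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestWelch:
    def test_hand_computed_example(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0, abs=1e-9)

    def test_identical_groups(self):
        t, df, p = welch_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [2.0, 3.0])

    def test_matches_satterthwaite_formula(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 2, 13)
        t, df, p = welch_t(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_ref = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert df == pytest.approx(df_ref, rel=1e-12)
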