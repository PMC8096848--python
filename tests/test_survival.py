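"""Dichotomization, Kaplan-Meier, log-rank, Cox and LASSO-Cox."""
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from gcsex.simulate import CohortConfig, generate_cohorts, generate_survival
from gcsex.survival import (
    combo_stratify,
    cox_fit,
    dichotomize,
    km_estimate,
    lasso_cox,
    logrank,
)


class TestDichotomize:
    def test_median_rule_on_1_to_10(self):
        labels, cutoff = dichotomize(np.arange(1, 11), "median")
        assert cutoff == 5.5
        assert (labels == "high").sum() == 5
        assert (labels == "low").sum() == 5

    def test_upper_quartile_on_8_distinct(self):
        labels, cutoff = dichotomize(np.arange(1, 9), "upper_quartile")
        assert (labels == "high").sum() == 2

    def test_ties_go_low(self):
        labels, cutoff = dichotomize(np.array([1, 1, 1, 2, 2, 10]), "median")
        # values equal to the cutoff are labelled low
        assert all(l == "low" for v, l in zip([1, 1, 1], labels[:3]))
        at_cut = np.array([1, 1, 1, 2, 2, 10])[labels == "low"]
        assert (at_cut <= cutoff).all()

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(np.full(10, 3.0))

    @pytest.mark.parametrize("rule", ["upper_tertile", "lower_tertile"])
    def test_tertile_rules_split_roughly_in_thirds(self, rule, rng):
        v = rng.normal(size=900)
        labels, _ = dichotomize(v, rule)
        frac_high = (labels == "high").mean()
        expect = 1 / 3 if rule == "upper_tertile" else 2 / 3
        assert frac_high == pytest.approx(expect, abs=0.02)


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        curve = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        assert curve.event_times.size == 0
        assert curve.survival_at(5.0) == 1.0

    def test_three_events_product_limit(self):
        curve = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(curve.at_risk, [3, 2, 1])

    def test_early_censoring_shrinks_risk_set(self):
        # censored at 0.5: first event at 1 uses risk set of 2 -> S = 1/2
        curve = km_estimate(np.array([0.5, 1.0, 2.0]), np.array([0, 1, 1]))
        np.testing.assert_allclose(curve.survival, [1 / 2, 0.0])
        np.testing.assert_allclose(curve.at_risk, [2, 1])

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=200)
        curve = km_estimate(t, np.ones(200, dtype=int))
        for q in (2.0, 5.0, 12.0):
            assert curve.survival_at(q) == pytest.approx((t > q).mean())

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(np.array([0.0, 1.0]), np.array([1, 1]))


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        g = np.array(["a"] * 3 + ["b"] * 3)
        chi2, p = logrank(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_tableau(self):
        # A: events at 1 and 4, censored 6; B: events at 2 and 5, censored 3.
        # O_A - E_A = 2 - 31/15 = -1/15, V = 433/450, chi2 = 2/433.
        t = np.array([1.0, 4.0, 6.0, 2.0, 5.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array(["A", "A", "A", "B", "B", "B"])
        chi2, _ = logrank(t, e, g)
        expect = float(Fraction(2, 433))
        assert chi2 == pytest.approx(expect, rel=1e-10)

    def test_symmetric_in_group_labels(self, rng):
        t = rng.exponential(5, size=40)
        e = (rng.random(40) < 0.8).astype(int)
        g = np.array(["x"] * 20 + ["y"] * 20)
        g_swapped = np.where(g == "x", "y", "x")
        assert logrank(t, e, g)[0] == pytest.approx(logrank(t, e, g_swapped)[0])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank(np.array([1.0, 2.0]), np.array([0, 0]), np.array(["a", "b"]))


class TestCoxFit:
    def test_planted_log_hr_recovered(self):
        cfg = CohortConfig(n_samples=2000, n_genes=5, n_y_linked=1,
                           n_xist_like=1, n_xci_escape=1)
        table = generate_cohorts(cfg, 1, seed=1)[0][1]
        rng = np.random.default_rng(1)
        x = (rng.random(2000) < 0.5).astype(float)
        out = generate_survival(table, x[None, :], np.array([np.log(1.5)]),
                                censor_rate=0.2, seed=1001)
        df = pd.DataFrame({"time": out.time, "event": out.event, "x": x})
        fit = cox_fit(df, ["x"])
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(1.5), abs=0.1)
        assert fit.hr[0] == pytest.approx(np.exp(fit.beta[0]))
        assert fit.ci_low[0] == pytest.approx(np.exp(fit.beta[0] - 1.96 * fit.se[0]))

    def test_null_covariate_ci_coverage_near_95(self):
        cover = 0
        reps = 150
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            n = 120
            t = rng.exponential(10, size=n)
            c = rng.exponential(40, size=n)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            x = rng.normal(size=n)
            fit = cox_fit(pd.DataFrame({"time": time, "event": event, "x": x}), ["x"])
            lo = fit.beta[0] - 1.96 * fit.se[0]
            hi = fit.beta[0] + 1.96 * fit.se[0]
            cover += lo <= 0.0 <= hi
        # binomial 99% band around 0.95 at 150 reps is ~ +-0.046
        assert cover / reps == pytest.approx(0.95, abs=0.05)

    def test_perfect_separation_flagged(self):
        # all events in the high-covariate group, strictly earlier
        df = pd.DataFrame({
            "time": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
            "event": [1, 1, 1, 0, 0, 0],
            "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        })
        fit = cox_fit(df, ["x"])
        assert not fit.converged

    def test_degenerate_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1], "x": [1.0, 1.0]})
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])


def _survival_data(seed, n=400, p=40, beta_idx=(3, 17), beta_val=0.6):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    for i, j in enumerate(beta_idx):
        beta[j] = beta_val * (1 if i % 2 == 0 else -1)
    lam = 0.05 * np.exp(X @ beta)
    t = rng.exponential(1 / lam)
    c = rng.exponential(1 / 0.012, n)
    return X, np.minimum(t, c), (t <= c).astype(int)


class TestLassoCox:
    def test_lambda_zero_endpoint_matches_unpenalized(self):
        X, time, event = _survival_data(0, n=300, p=5, beta_idx=(1,))
        res = lasso_cox(X, time, event, lambda_path=np.array([0.1, 0.0]),
                        n_folds=0)
        names = [f"f{j}" for j in range(5)]
        df = pd.DataFrame(X, columns=names)
        df["time"], df["event"] = time, event
        fit = cox_fit(df, names)
        np.testing.assert_allclose(res.coef_path[-1], fit.beta, atol=1e-4)

    def test_large_lambda_gives_empty_model(self):
        X, time, event = _survival_data(1, n=200, p=10, beta_idx=(3, 7))
        res = lasso_cox(X, time, event, lambda_path=np.array([10.0]), n_folds=0)
        np.testing.assert_array_equal(res.coef_path[0], 0.0)

    def test_support_size_grows_as_lambda_decreases(self):
        X, time, event = _survival_data(2, n=300, p=20)
        res = lasso_cox(X, time, event, n_folds=0)
        nnz = (res.coef_path != 0).sum(axis=1)
        # monotone along the decreasing path, within one-feature wiggle
        assert nnz[0] <= 1
        assert nnz[-1] >= nnz[0]
        assert (np.diff(nnz) >= -1).all()

    def test_planted_features_selected_at_cv_optimum(self):
        hits = 0
        reps = 8
        for rep in range(reps):
            X, time, event = _survival_data(100 + rep)
            res = lasso_cox(X, time, event, n_folds=10, seed=rep)
            hits += {"f3", "f17"} <= set(res.selected)
        assert hits >= int(np.ceil(0.9 * reps))

    def test_fewer_events_than_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        time = np.arange(1.0, 21.0)
        event = np.zeros(20, dtype=int)
        event[:5] = 1
        with pytest.raises(ValueError):
            lasso_cox(X, time, event, n_folds=10)


class TestComboStratify:
    def test_group_sizes_sum_to_n(self, rng):
        ar = rng.normal(size=200)
        mir = rng.normal(size=200)
        four, merged = combo_stratify(ar, mir)
        assert len(four) == 200
        import collections
        counts = collections.Counter(four)
        assert sum(counts.values()) == 200
        assert set(counts) <= {"both-low", "AR-high/miR-low",
                               "AR-low/miR-high", "both-high"}

    def test_both_high_iff_high_under_each_rule(self, rng):
        ar = rng.normal(size=100)
        mir = rng.normal(size=100)
        four, merged = combo_stratify(ar, mir)
        ar_hi = dichotomize(ar, "median")[0] == "high"
        mir_hi = dichotomize(mir, "upper_quartile")[0] == "high"
        np.testing.assert_array_equal(four == "both-high", ar_hi & mir_hi)

    def test_merged_binary_preserves_both_high(self, rng):
        ar = rng.normal(size=150)
        mir = rng.normal(size=150)
        four, merged = combo_stratify(ar, mir)
        assert set(merged) <= {"both-high", "rest"}
        assert (merged == "both-high").sum() == (four == "both-high").sum()
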