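"""Survival statistics against brute-force oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import BaseEstimator

from tgand.survival import (
    ConfusionCounts,
    CVPlan,
    SurvivalData,
    abc_metric,
    confusion_metrics,
    cox_hazard_ratio,
    crossval_pool,
    km_auc,
    km_estimate,
    logrank_test,
    make_cv_plan,
)


# ---------------------------------------------------------------------------
# independent oracles (deliberately un-vectorised)
# ---------------------------------------------------------------------------


def km_oracle(times, events, horizon=120.0):
    """Product-limit survival by explicit risk-set enumeration."""
    events = [0 if t > horizon else e for t, e in zip(times, events)]
    times = [min(t, horizon) for t in times]
    pairs = sorted(zip(times, events))
    s = 1.0
    out = []
    for t in sorted({t for t, e in pairs if e == 1}):
        n_at_risk = sum(1 for ti, _ in pairs if ti >= t)
        d = sum(1 for ti, ei in pairs if ti == t and ei == 1)
        s *= 1.0 - d / n_at_risk
        out.append((t, s))
    return out


def logrank_oracle(t1, e1, t2, e2, horizon=120.0):
    """O/E/V tabulation over pooled risk sets, subject by subject."""
    def trunc(ts, es):
        return ([min(t, horizon) for t in ts],
                [0 if t > horizon else e for t, e in zip(list(ts), es)])

    t1, e1 = trunc(t1, e1)
    t2, e2 = trunc(t2, e2)
    all_t = sorted({t for t, e in zip(t1 + t2, e1 + e2) if e == 1})
    O = E = V = 0.0
    for t in all_t:
        n1 = sum(1 for ti in t1 if ti >= t)
        n2 = sum(1 for ti in t2 if ti >= t)
        d1 = sum(1 for ti, ei in zip(t1, e1) if ti == t and ei == 1)
        d2 = sum(1 for ti, ei in zip(t2, e2) if ti == t and ei == 1)
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return chi2, float(stats.chi2.sf(chi2, 1))


def auc_oracle(data: SurvivalData, horizon=120.0, dt=0.005):
    """Riemann integral of the KM step curve on a fine grid."""
    curve = km_estimate(data, horizon)
    grid = np.arange(0.0, horizon, dt)
    return float(sum(curve.at(t) * dt for t in grid))


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------


class TestKMEstimate:
    def test_all_censored_curve_stays_at_one(self):
        d = SurvivalData([10, 20, 30], [0, 0, 0])
        curve = km_estimate(d)
        assert curve.event_times.size == 0
        assert curve.at(0) == 1.0 and curve.at(119) == 1.0

    def test_single_event_among_four(self):
        d = SurvivalData([10, 50, 60, 70], [1, 0, 0, 0])
        curve = km_estimate(d)
        assert curve.at(10) == pytest.approx(0.75)

    def test_hand_computed_mixed_table(self):
        # 8 subjects; risk-set products worked out by hand:
        # t=1 (n=8): 7/8; t=2 (n=7): *6/7 = 0.75; t=3 (n=5): *4/5 = 0.6;
        # t=6 (n=3): *2/3 = 0.4
        d = SurvivalData([1, 2, 2, 3, 5, 6, 8, 9], [1, 0, 1, 1, 0, 1, 0, 0])
        curve = km_estimate(d)
        assert list(curve.event_times) == [1, 2, 3, 6]
        assert np.allclose(curve.survival, [0.875, 0.75, 0.6, 0.4])

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(1, 13)
            times = rng.integers(0, 150, n).astype(float)
            events = rng.integers(0, 2, n)
            d = SurvivalData(times, events)
            curve = km_estimate(d)
            oracle = km_oracle(times.tolist(), events.tolist())
            assert len(curve.event_times) == len(oracle)
            for (t, s), tt, ss in zip(oracle, curve.event_times, curve.survival):
                assert t == tt and s == pytest.approx(ss)

    def test_followup_beyond_horizon_censored_at_horizon(self):
        d = SurvivalData([50, 130, 200], [1, 1, 1])
        curve = km_estimate(d, horizon=120)
        assert list(curve.event_times) == [50]

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            SurvivalData([-1, 3], [1, 0])


class TestKMAuc:
    def test_flat_curve_area_is_horizon(self):
        curve = km_estimate(SurvivalData([150, 150], [0, 0]))
        assert km_auc(curve) == pytest.approx(120.0)

    def test_drop_to_zero_at_sixty(self):
        curve = km_estimate(SurvivalData([60, 60, 60], [1, 1, 1]))
        assert km_auc(curve) == pytest.approx(60.0)

    def test_half_survival_from_time_zero(self):
        curve = km_estimate(SurvivalData([0, 150], [1, 0]))
        assert km_auc(curve) == pytest.approx(60.0)

    def test_matches_fine_grid_integration(self):
        rng = np.random.default_rng(1)
        d = SurvivalData(rng.uniform(0, 200, 20), rng.integers(0, 2, 20))
        assert km_auc(km_estimate(d)) == pytest.approx(auc_oracle(d), abs=0.05)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        d = ([5, 15, 40, 80], [1, 0, 1, 1])
        chi2, p = logrank_test(SurvivalData(*d), SurvivalData(*d))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_frozen_hand_tabulation(self):
        # a: events 1,2,3; b: events 6,7,8 (all uncensored).
        # Risk sets give O=3, E=0.5+0.4+0.25=1.15,
        # V=0.25+0.24+0.1875=0.6775 -> chi2 = 1.85^2/0.6775
        chi2, p = logrank_test(SurvivalData([1, 2, 3], [1, 1, 1]),
                               SurvivalData([6, 7, 8], [1, 1, 1]))
        assert chi2 == pytest.approx(1.85 ** 2 / 0.6775, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(1.85 ** 2 / 0.6775, 1), rel=1e-12)

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n1, n2 = rng.integers(1, 7, 2)
            d1 = (rng.integers(0, 150, n1).astype(float), rng.integers(0, 2, n1))
            d2 = (rng.integers(0, 150, n2).astype(float), rng.integers(0, 2, n2))
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    chi2, p = logrank_test(SurvivalData(*d1), SurvivalData(*d2))
            c_o, p_o = logrank_oracle(list(d1[0]), list(d1[1]),
                                      list(d2[0]), list(d2[1]))
            assert chi2 == pytest.approx(c_o, abs=1e-10)
            assert p == pytest.approx(p_o, abs=1e-10)

    def test_symmetric_in_group_order(self):
        a = SurvivalData([3, 9, 40, 100], [1, 1, 0, 1])
        b = SurvivalData([20, 60, 110], [1, 0, 1])
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_invariant_to_censoring_after_last_event(self):
        a = SurvivalData([3, 9, 40], [1, 1, 1])
        b1 = SurvivalData([20, 60, 90], [1, 1, 0])
        b2 = SurvivalData([20, 60, 119], [1, 1, 0])
        assert logrank_test(a, b1) == pytest.approx(logrank_test(a, b2))

    def test_no_events_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank_test(SurvivalData([5, 10], [0, 0]),
                                   SurvivalData([7], [0]))
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(SurvivalData([], []), SurvivalData([1], [1]))

    def test_p_value_against_permutation_null(self):
        """Asymptotic chi-square p agrees with the 2000-draw permutation
        distribution of the statistic on a 12-subject dataset."""
        times = np.array([4, 9, 13, 20, 31, 45, 58, 70, 84, 99, 110, 118], float)
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0, 1, 1])
        group = np.array([0, 0, 1, 0, 0, 1, 1, 0, 1, 1, 1, 0])

        def stat(g):
            a = SurvivalData(times[g == 0], events[g == 0])
            b = SurvivalData(times[g == 1], events[g == 1])
            return logrank_test(a, b)[0]

        observed_chi2, p_asym = logrank_test(
            SurvivalData(times[group == 0], events[group == 0]),
            SurvivalData(times[group == 1], events[group == 1]))
        rng = np.random.default_rng(7)
        draws = np.array([stat(rng.permutation(group)) for _ in range(2000)])
        p_perm = float((draws >= observed_chi2 - 1e-12).mean())
        mc_sigma = np.sqrt(p_perm * (1 - p_perm) / 2000)
        # 3 sigma Monte-Carlo band plus a small allowance for the
        # chi-square approximation at n = 12
        assert abs(p_asym - p_perm) < 3 * mc_sigma + 0.05


# ---------------------------------------------------------------------------
# ABC and confusion metrics
# ---------------------------------------------------------------------------


def _random_survival(rng, n):
    return SurvivalData(rng.uniform(0, 200, n), rng.integers(0, 2, n))


class TestAbcMetric:
    def test_perfect_prediction_zeroes_outer_components(self):
        rng = np.random.default_rng(3)
        low, high = _random_survival(rng, 10), _random_survival(rng, 8)
        triple = abc_metric(low, low, high, high)
        assert triple[0] == pytest.approx(0.0)
        assert triple[2] == pytest.approx(0.0)

    def test_identical_predicted_groups_zero_middle(self):
        rng = np.random.default_rng(4)
        whole = _random_survival(rng, 12)
        low, high = _random_survival(rng, 6), _random_survival(rng, 6)
        triple = abc_metric(low, whole, whole, high)
        assert triple[1] == pytest.approx(0.0)

    def test_matches_step_integral_oracle(self):
        rng = np.random.default_rng(5)
        groups = [_random_survival(rng, 5) for _ in range(4)]
        triple = abc_metric(*groups)
        aucs = [auc_oracle(g) for g in groups]
        expect = (aucs[0] - aucs[1], aucs[1] - aucs[2], aucs[2] - aucs[3])
        assert np.allclose(triple, expect, atol=0.2)

    def test_telescoping_identity(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            groups = [_random_survival(rng, rng.integers(3, 9)) for _ in range(4)]
            triple = abc_metric(*groups)
            total = km_auc(km_estimate(groups[0])) - km_auc(km_estimate(groups[3]))
            assert sum(triple) == pytest.approx(total, abs=1e-9)

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(7)
        g = _random_survival(rng, 4)
        with pytest.raises(ValueError):
            abc_metric(g, SurvivalData([], []), g, g)


class TestConfusionMetrics:
    def test_arithmetic_example(self):
        acc, sens, spec = confusion_metrics(ConfusionCounts(tp=8, fp=4, tn=6, fn=2))
        assert (acc, sens, spec) == (0.7, 0.8, 0.6)

    def test_no_false_negatives_gives_perfect_sensitivity(self):
        _, sens, _ = confusion_metrics(ConfusionCounts(tp=5, fp=1, tn=3, fn=0))
        assert sens == 1.0

    def test_undefined_sensitivity_flagged(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            _, sens, _ = confusion_metrics(ConfusionCounts(tp=0, fp=2, tn=3, fn=0))
        assert sens is None

    def test_accuracy_decomposition_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            c = ConfusionCounts(*rng.integers(1, 30, 4))
            acc, sens, spec = confusion_metrics(c)
            P, N = c.tp + c.fn, c.tn + c.fp
            assert acc == pytest.approx((sens * P + spec * N) / c.n)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


def cox_newton_raphson_oracle(times, events, x, iters=50):
    """Univariate Breslow partial-likelihood Newton–Raphson."""
    beta = 0.0
    order = np.argsort(times)
    times, events, x = np.asarray(times)[order], np.asarray(events)[order], np.asarray(x)[order]
    for _ in range(iters):
        U = H = 0.0
        for i in range(len(times)):
            if events[i] != 1:
                continue
            risk = times >= times[i]
            w = np.exp(beta * x[risk])
            xbar = (w * x[risk]).sum() / w.sum()
            x2bar = (w * x[risk] ** 2).sum() / w.sum()
            U += x[i] - xbar
            H += x2bar - xbar ** 2
        beta += U / H
    return beta


class TestCoxHazardRatio:
    def test_identical_groups_hr_near_one(self):
        times = [10, 20, 30, 40, 50, 60] * 2
        events = [1, 0, 1, 1, 0, 1] * 2
        grp = [0] * 6 + [1] * 6
        df = pd.DataFrame({"time": times, "event": events, "grp": grp})
        res = cox_hazard_ratio(df, ["grp"])
        assert res["converged"]
        cov = res["covariates"]["grp"]
        assert cov["ci_low"] < 1.0 < cov["ci_high"]

    def test_matches_newton_raphson_on_breslow_likelihood(self):
        times = [2, 4, 6, 8, 10, 12]
        events = [1, 1, 1, 1, 1, 0]
        grp = [1, 1, 0, 1, 0, 0]
        beta = cox_newton_raphson_oracle(times, events, grp)
        df = pd.DataFrame({"time": times, "event": events, "grp": grp})
        res = cox_hazard_ratio(df, ["grp"])
        assert res["covariates"]["grp"]["hr"] == pytest.approx(np.exp(beta), rel=1e-4)

    def test_simulated_hr_two_is_covered_by_ci(self):
        """Exponential arms with true HR 2: 95% Wald CI covers the truth in
        at least 90% of 50 replicates."""
        covered = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 500
            t0 = rng.exponential(1 / 0.01, n)
            t1 = rng.exponential(1 / 0.02, n)
            cens = 300.0
            times = np.concatenate([np.minimum(t0, cens), np.minimum(t1, cens)])
            events = np.concatenate([t0 <= cens, t1 <= cens]).astype(int)
            grp = np.concatenate([np.zeros(n), np.ones(n)])
            df = pd.DataFrame({"time": times, "event": events, "grp": grp})
            res = cox_hazard_ratio(df, ["grp"])
            cov = res["covariates"]["grp"]
            if cov["ci_low"] <= 2.0 <= cov["ci_high"]:
                covered += 1
        assert covered >= 45

    def test_multivariate_mode_reports_each_covariate(self):
        rng = np.random.default_rng(9)
        n = 120
        grp = rng.integers(0, 2, n)
        er = rng.integers(0, 2, n)
        times = rng.exponential(100 / (1 + grp), n)
        df = pd.DataFrame({"time": times, "event": np.ones(n, int),
                           "predicted_high": grp, "er": er})
        res = cox_hazard_ratio(df, ["predicted_high", "er"])
        assert set(res["covariates"]) == {"predicted_high", "er"}


# ---------------------------------------------------------------------------
# pooled cross-validation
# ---------------------------------------------------------------------------


class _OracleEstimator(BaseEstimator):
    """Looks the true label up by image bytes — a perfect, deterministic
    'trainer' for integrity checks."""

    def __init__(self, lookup=None):
        self.lookup = lookup

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = np.array([self.lookup[x.tobytes()] for x in np.asarray(X, np.float32)])
        return np.column_stack([1.0 - p, p])


def _cv_problem(n=100, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, (n, 8, 8)).astype(np.float32)
    y = (np.arange(n) % 2).astype(np.int64)
    times = np.where(y == 1, rng.uniform(5, 100, n), rng.uniform(120, 200, n))
    events = np.where(y == 1, 1, 0)
    return X, y, SurvivalData(times, events)


class TestCrossvalPool:
    def test_each_patient_predicted_exactly_once(self):
        X, y, surv = _cv_problem()
        plan = make_cv_plan(y, k=5, seed=1)
        assert all((plan.fold_of == f).sum() == 20 for f in range(5))
        lookup = {x.tobytes(): float(t) for x, t in zip(X, y)}
        report = crossval_pool(X, y, surv, plan, _OracleEstimator(lookup))
        assert len(report.predictions) == 100
        assert report.predictions.patient_id.is_unique

    def test_oracle_trainer_attains_perfect_metrics(self):
        X, y, surv = _cv_problem()
        plan = make_cv_plan(y, k=5, seed=1)
        lookup = {x.tobytes(): float(t) for x, t in zip(X, y)}
        report = crossval_pool(X, y, surv, plan, _OracleEstimator(lookup))
        assert report.accuracy == 1.0
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0
        assert report.logrank_p < 1e-6

    def test_reproducible_given_plan_seed(self):
        X, y, surv = _cv_problem()
        lookup = {x.tobytes(): float(t) for x, t in zip(X, y)}
        reports = []
        for _ in range(2):
            plan = make_cv_plan(y, k=5, seed=3)
            reports.append(crossval_pool(X, y, surv, plan, _OracleEstimator(lookup)))
        pd.testing.assert_frame_equal(reports[0].predictions, reports[1].predictions)

    def test_extra_train_overlap_rejected(self):
        X, y, surv = _cv_problem()
        plan = make_cv_plan(y, k=5, seed=1)
        lookup = {x.tobytes(): float(t) for x, t in zip(X, y)}
        ids = [str(i) for i in range(len(X))]
        with pytest.raises(ValueError, match="overlap"):
            crossval_pool(X, y, surv, plan, _OracleEstimator(lookup),
                          patient_ids=ids,
                          extra_train=(X[:5], y[:5], ids[:5]))

    def test_plan_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            CVPlan(3, np.array([0, 0, 2, 2]), 0)

    def test_report_json_serialisable(self, tmp_path):
        import json

        X, y, surv = _cv_problem(40)
        plan = make_cv_plan(y, k=5, seed=1)
        lookup = {x.tobytes(): float(t) for x, t in zip(X, y)}
        report = crossval_pool(X, y, surv, plan, _OracleEstimator(lookup))
        path = tmp_path / "report.json"
        report.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["accuracy"] == 1.0
        assert len(payload["abc"]) == 3
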