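"""Unit and property tests for the hand-built survival statistics,
including cross-checks against lifelines / scikit-survival / scikit-learn
as independent reference implementations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from prognosig.survival import (
    MONOTONE_BETA_BOUND,
    CoxData,
    PreparedCox,
    concordance_index,
    km_estimate,
    logrank_test,
    mann_whitney_auc,
    roc_auc,
)

from conftest import make_cohort
from prognosig.survival import fit_cox


# ---------------------------------------------------------------------------
# independent oracles (naive loops, no shared code with the implementation)
# ---------------------------------------------------------------------------


def naive_breslow_loglik(beta, times, events, x):
    """Direct O(n^2) Breslow log partial likelihood for one covariate."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = x[times >= times[i]]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * risk)))
    return ll


def grid_maximize_beta(times, events, x, lo=-15.0, hi=15.0):
    grid = np.arange(lo, hi, 0.01)
    vals = [naive_breslow_loglik(b, times, events, x) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    res = minimize_scalar(
        lambda b: -naive_breslow_loglik(b, times, events, x),
        bounds=(b0 - 0.02, b0 + 0.02),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------


class TestCox:
    def test_interleaved_binary_toy(self):
        cohort = make_cohort([1, 2, 3, 4], [1, 1, 1, 1], [[1.0, 0.0, 1.0, 0.0]])
        fit = fit_cox(cohort, ["g0"])
        assert fit.converged
        t, e, x = np.array([1.0, 2, 3, 4]), np.array([1, 1, 1, 1]), np.array([1.0, 0, 1, 0])
        assert fit.coefficients[0] == pytest.approx(grid_maximize_beta(t, e, x), abs=1e-4)
        assert fit.coefficients[0] == pytest.approx(0.94, abs=0.01)

    def test_perfect_separation_flagged(self):
        cohort = make_cohort([1, 2, 3, 4], [1, 1, 1, 1], [[1.0, 1.0, 0.0, 0.0]])
        fit = fit_cox(cohort, ["g0"])
        assert not fit.converged
        assert abs(fit.coefficients[0]) > MONOTONE_BETA_BOUND

    def test_constant_zero_covariate(self):
        cohort = make_cohort([1, 2, 3, 4], [1, 1, 0, 1], np.zeros((1, 4)))
        fit = fit_cox(cohort, ["g0"])
        assert fit.converged
        assert fit.coefficients[0] == 0.0
        assert fit.wald_p[0] == 1.0

    def test_no_events_is_error(self):
        with pytest.raises(ValueError, match="event"):
            fit_cox(make_cohort([1, 2, 3], [0, 0, 0]), ["g0"])

    def test_overfit_guard(self, null_cohort):
        small = null_cohort.subset_samples(null_cohort.sample_ids[:12])
        if small.events.sum() == 0:
            pytest.skip("subset carries no events")
        with pytest.raises(ValueError, match="overfit"):
            fit_cox(small, small.gene_ids[:5])

    def test_matches_grid_oracle_on_random_small_cohorts(self):
        """Newton fit equals brute-force maximization on tie-free 1-covariate
        cohorts (where Efron and Breslow likelihoods coincide)."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(60):
            n = int(rng.integers(5, 11))
            times = rng.uniform(1, 100, n)
            events = (rng.random(n) < 0.8).astype(float)
            if events.sum() == 0:
                events[rng.integers(n)] = 1
            x = rng.uniform(0, 4, n)
            prepared = PreparedCox(times, events, x[:, None], ["g"])
            fit = prepared.fit([0])
            if not fit.converged:
                continue
            assert fit.coefficients[0] == pytest.approx(
                grid_maximize_beta(times, events, x), abs=1e-3
            )
            checked += 1
        assert checked >= 40

    def test_matches_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        n = 120
        X = rng.uniform(0, 4, size=(n, 3))
        eta = X @ np.array([0.5, -0.4, 0.0])
        times = np.ceil(rng.exponential(np.exp(-eta)) * 30) + 1
        events = (rng.random(n) < 0.7).astype(float)
        events[np.argmax(times)] = 1
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = times, events
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        mine = PreparedCox(times, events, X, ["a", "b", "c"]).fit(["a", "b", "c"])
        np.testing.assert_allclose(mine.coefficients, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(
            mine.standard_errors, cph.standard_errors_.values, atol=1e-5
        )
        assert mine.log_partial_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_wald_identity(self):
        cohort = make_cohort(
            np.arange(1, 31), [1] * 20 + [0] * 10, [np.linspace(0, 3, 30)]
        )
        fit = fit_cox(cohort, ["g0"])
        assert fit.wald_z[0] == pytest.approx(
            fit.coefficients[0] / fit.standard_errors[0]
        )

    def test_cox_data_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            CoxData(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            CoxData(np.array([1.0, 2.0]), np.array([2.0, 0.0]))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKM:
    def test_hand_product_limit(self):
        km = km_estimate([5, 10, 15], [0, 1, 1])
        assert km.survival_at(10) == pytest.approx(0.5)
        assert km.survival_at(15) == pytest.approx(0.0)

    def test_single_death_among_censored(self):
        km = km_estimate([2, 5, 6, 7], [1, 0, 0, 0])
        assert km.survival_at(2) == pytest.approx(3 / 4)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = rng.uniform(1, 50, 40)
        km = km_estimate(times, np.ones(40))
        for k, t in enumerate(np.sort(times)):
            assert km.survival_at(t) == pytest.approx((40 - k - 1) / 40)

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(8)
        times = np.ceil(rng.exponential(20, 100)) + 1
        events = (rng.random(100) < 0.6).astype(int)
        events[0] = 1
        km = km_estimate(times, events)
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert np.all(np.diff(km.n_at_risk) <= 0)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


class TestLogRank:
    def test_identical_groups(self):
        r = logrank_test([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        assert r.chi_square == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_four_subject_hand_oracle(self):
        # O=2, E=5/6, V=17/36 summed over the four event times
        r = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert r.chi_square == pytest.approx(49 / 17, abs=1e-10)

    def test_eventless_group_in_risk_sets(self):
        r = logrank_test([10, 20], [0, 0], [5, 15], [1, 1])
        assert np.isfinite(r.chi_square)
        assert 0 < r.p_value <= 1

    def test_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(17)
        ta = np.ceil(rng.exponential(10, 60)) + 1
        tb = np.ceil(rng.exponential(14, 50)) + 1
        ea = (rng.random(60) < 0.7).astype(int)
        eb = (rng.random(50) < 0.7).astype(int)
        ea[0] = eb[0] = 1
        ref = lifelines_stats.logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        mine = logrank_test(ta, ea, tb, eb)
        assert mine.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="variance"):
            r = logrank_test([5], [1], [1], [0])
        assert r.p_value == 1.0


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


class TestConcordance:
    def test_perfect_ordering(self):
        r = concordance_index([1, 2, 3], [1, 1, 1], [3, 2, 1])
        assert r.c_index == 1.0
        assert r.comparable_pairs == 3

    def test_toy_enumeration(self):
        r = concordance_index([2, 5, 4], [1, 0, 1], [2, 1, 3])
        assert r.c_index == pytest.approx(2 / 3)
        assert r.comparable_pairs == 3

    def test_all_tied_scores(self):
        r = concordance_index([1, 2, 3], [1, 1, 1], [5, 5, 5])
        assert r.c_index == pytest.approx(0.5)

    def test_no_comparable_pairs_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([3, 3], [1, 1], [1, 2])

    def test_matches_scikit_survival(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(23)
        n = 150
        times = rng.uniform(1, 100, n)  # tie-free
        events = (rng.random(n) < 0.6).astype(bool)
        events[np.argmax(times)] = True
        scores = rng.normal(size=n)
        ref = sksurv_metrics.concordance_index_censored(events, times, scores)[0]
        mine = concordance_index(times, events.astype(float), scores)
        assert mine.c_index == pytest.approx(ref, abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        times = rng.uniform(1, 50, n)
        events = (rng.random(n) < 0.7).astype(float)
        if events.sum() == 0:
            events[0] = 1
        scores = rng.normal(size=n)
        base = concordance_index(times, events, scores).c_index
        warped = concordance_index(times, events, np.exp(2 * scores) + 7).c_index
        assert base == pytest.approx(warped, abs=1e-12)


# ---------------------------------------------------------------------------
# ROC-AUC
# ---------------------------------------------------------------------------


class TestROC:
    def test_toy_pair_enumeration(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.1, 0.2]).auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        r = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert r.auc == 1.0

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.normal(size=50).round(1)  # force some ties
        assert roc_auc(labels, scores).auc + roc_auc(labels, -scores).auc == 1.0

    def test_matches_sklearn_with_ties(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(13)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = rng.normal(size=200).round(1)
        mine = roc_auc(labels, scores)
        assert mine.auc == pytest.approx(sk.roc_auc_score(labels, scores), abs=1e-12)
        assert mann_whitney_auc(labels, scores) == mine.auc

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(31)
        labels = np.repeat([0, 1], 50)
        scores = rng.normal(size=100) + labels
        r = roc_auc(labels, scores)
        assert r.ci_low <= r.auc <= r.ci_high
        assert r.p_value < 0.001  # strong signal


def test_efron_equals_breslow_without_ties():
    """Tie-free data: the Efron correction vanishes, so the fit agrees with
    an explicit Breslow maximization."""
    rng = np.random.default_rng(44)
    n = 60
    times = rng.uniform(1, 1000, n)
    events = (rng.random(n) < 0.7).astype(float)
    events[0] = 1
    x = rng.uniform(0, 3, n)
    fit = PreparedCox(times, events, x[:, None], ["g"]).fit([0])
    assert fit.converged
    assert fit.coefficients[0] == pytest.approx(
        grid_maximize_beta(times, events, x), abs=1e-4
    )
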