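"""Survival statistics implemented from first principles.

This module is the computational core of the package: Cox proportional-hazards
fitting by Newton-Raphson on the Efron-tie-corrected partial likelihood,
the Kaplan-Meier product-limit estimator, the two-group log-rank test,
Harrell's concordance index, and the binary ROC-AUC with a DeLong variance
estimator.  Everything here is hand-authored; external survival libraries are
used only as independent cross-checks in the test suite.

Conventions
-----------
* ``times`` are strictly positive follow-up times (days), ``events`` are
  1 = death observed, 0 = right-censored.
* A "risk score" is any real-valued predictor where larger means higher
  hazard.
* Wald P-values are two-sided standard-normal tail probabilities of
  z = coefficient / SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CoxFit",
    "CoxData",
    "PreparedCox",
    "KMCurve",
    "LogRankResult",
    "ConcordanceResult",
    "ROCResult",
    "fit_cox",
    "km_estimate",
    "logrank_test",
    "concordance_index",
    "roc_auc",
    "mann_whitney_auc",
]

#: Coefficient magnitude beyond which a fit is declared non-convergent
#: (monotone likelihood / perfect separation).  On the log-hazard scale a
#: per-unit-expression effect of e^20 is far outside anything estimable.
MONOTONE_BETA_BOUND = 20.0

#: Standard error beyond which a "converged" fit is reclassified as
#: degenerate: the observed information has collapsed to ~0, which happens
#: when a flat monotone likelihood lets the score underflow before the
#: coefficient reaches MONOTONE_BETA_BOUND.
MONOTONE_SE_BOUND = 1e3


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoxFit:
    """Result of one Cox proportional-hazards fit.

    Coefficients are log hazard ratios per unit of (log-scale) expression.
    ``converged=False`` marks fits abandoned on monotone likelihood or
    iteration exhaustion; their coefficients are reported as-is and callers
    (e.g. the signature search) are expected to skip them.
    """

    gene_ids: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    log_partial_likelihood: float
    converged: bool
    n_iterations: int

    def __post_init__(self) -> None:
        k = len(self.gene_ids)
        for name in ("coefficients", "standard_errors", "wald_z", "wald_p"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} length does not match gene_ids")

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.gene_ids),
            "coefficients": [float(c) for c in self.coefficients],
            "standard_errors": [float(s) for s in self.standard_errors],
            "wald_z": [float(z) for z in self.wald_z],
            "wald_p": [float(p) for p in self.wald_p],
            "log_partial_likelihood": float(self.log_partial_likelihood),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
        }


class CoxData:
    """Sorted risk-set structure shared by every Cox fit on one cohort.

    Sorting the follow-up times and locating tied-event groups once lets the
    exhaustive signature search run millions of small fits without repeating
    the O(n log n) setup.
    """

    def __init__(self, times: np.ndarray, events: np.ndarray) -> None:
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=float)
        if times.shape != events.shape or times.ndim != 1:
            raise ValueError("times and events must be equal-length 1-d arrays")
        if times.size == 0:
            raise ValueError("empty cohort")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("survival times must be finite and strictly positive")
        if not np.all(np.isin(events, (0.0, 1.0))):
            raise ValueError("events must be 0 (censored) or 1 (death)")
        if events.sum() == 0:
            raise ValueError("cohort contains no events; survival statistics degenerate")

        order = np.argsort(times, kind="stable")
        self.order = order
        self.time = times[order]
        self.event = events[order]
        self.n = times.size

        # unique follow-up times; reduceat boundaries for tied-group sums
        _, first = np.unique(self.time, return_index=True)
        deaths_per_time = np.add.reduceat(self.event, first)
        keep = deaths_per_time > 0
        self.group_first = first
        self.event_groups = keep
        self.risk_start = first[keep]  # risk set at event time j = sorted[start_j:]
        self.n_deaths = deaths_per_time[keep]
        self.max_ties = int(self.n_deaths.max())
        self.death_mask = self.event.astype(bool)
        self.n_events_total = int(self.event.sum())


def _rev_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _efron_quantities(
    X: np.ndarray, beta: np.ndarray, data: CoxData
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron-corrected log partial likelihood, score vector and information.

    ``X`` must already be in ``data``'s sorted sample order.  The linear
    predictor is centred before exponentiation; the shift cancels exactly in
    the partial likelihood (one log-denominator per death), so the returned
    value equals the uncentred log partial likelihood.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.mean()
    w = np.exp(np.clip(eta, -500.0, 500.0))
    e = data.event

    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    r0 = _rev_cumsum(w)[data.risk_start]
    r1 = _rev_cumsum(wx)[data.risk_start]
    r2 = _rev_cumsum(wxx)[data.risk_start]

    s0 = np.add.reduceat(w * e, data.group_first)[data.event_groups]
    s1 = np.add.reduceat(wx * e[:, None], data.group_first, axis=0)[data.event_groups]
    s2 = np.add.reduceat(wxx * e[:, None, None], data.group_first, axis=0)[
        data.event_groups
    ]

    ll = float(eta @ e)
    score = X[data.death_mask].sum(axis=0).astype(float)
    info = np.zeros((p, p))
    d = data.n_deaths
    for tie_rank in range(data.max_ties):
        m = d > tie_rank
        frac = tie_rank / d[m]
        phi0 = r0[m] - frac * s0[m]
        ll -= float(np.log(phi0).sum())
        u = (r1[m] - frac[:, None] * s1[m]) / phi0[:, None]
        score -= u.sum(axis=0)
        phi2 = (r2[m] - frac[:, None, None] * s2[m]) / phi0[:, None, None]
        info += phi2.sum(axis=0) - u.T @ u
    return ll, score, info


def _newton_cox(
    X_sorted: np.ndarray, data: CoxData, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Newton-Raphson with step-halving on the Efron partial likelihood.

    Returns (beta, information, loglik, converged, n_iterations).
    """
    p = X_sorted.shape[1]
    beta = np.zeros(p)
    ll, score, info = _efron_quantities(X_sorted, beta, data)
    converged = np.max(np.abs(score)) < tol  # e.g. constant-zero covariate
    n_iter = 0
    if converged:
        return beta, info, ll, True, 0

    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        factor = 1.0
        improved = False
        for _ in range(40):
            cand = beta + factor * step
            cll, cscore, cinfo = _efron_quantities(X_sorted, cand, data)
            if np.isfinite(cll) and cll >= ll - 1e-12:
                improved = True
                break
            factor *= 0.5
        if not improved:
            break  # likelihood cannot be improved along the Newton direction
        delta = np.max(np.abs(cand - beta))
        beta, ll, score, info = cand, cll, cscore, cinfo
        if np.max(np.abs(beta)) > MONOTONE_BETA_BOUND:
            # monotone likelihood: coefficient marching to infinity
            return beta, info, ll, False, n_iter
        # A small score only signals an interior maximum if the parameter
        # step has also collapsed; under monotone likelihood the score
        # vanishes while beta still advances by O(1) per iteration.
        if delta < tol or (np.max(np.abs(score)) < tol and delta < 1e-2):
            converged = True
            break
    return beta, info, ll, converged, n_iter


class PreparedCox:
    """A cohort pre-sorted for repeated Cox fits over gene subsets.

    Build once, then call :meth:`fit` with column indices (or gene IDs) for
    each candidate combination — the pattern used by the univariate screen and
    the exhaustive search.
    """

    def __init__(self, times, events, X, gene_ids: Sequence[str]) -> None:
        self.data = CoxData(np.asarray(times, float), np.asarray(events, float))
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.data.n:
            raise ValueError("design matrix rows must match sample count")
        self.X_sorted = np.ascontiguousarray(X[self.data.order])
        self.gene_ids = list(gene_ids)
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @classmethod
    def from_cohort(cls, cohort) -> "PreparedCox":
        expr = cohort.expression.data
        return cls(cohort.times, cohort.events, expr.to_numpy().T, list(expr.index))

    def fit(
        self, genes: Sequence[str | int], max_iter: int = 100, tol: float = 1e-9
    ) -> CoxFit:
        idx = [g if isinstance(g, (int, np.integer)) else self._index[g] for g in genes]
        if len(idx) == 0:
            raise ValueError("at least one gene is required")
        if len(idx) > max(1.0, self.data.n / 5):
            raise ValueError(
                f"{len(idx)} covariates for {self.data.n} samples exceeds the "
                "1-per-5-samples overfitting guard"
            )
        Xs = self.X_sorted[:, idx]
        beta, info, ll, converged, n_iter = _newton_cox(Xs, self.data, max_iter, tol)
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        if converged and np.any(beta != 0):
            # flat likelihood = observed information collapsed: the SE either
            # explodes or, when the information underflows to 0, pinv makes it 0
            degenerate = ~np.isfinite(se) | (se > MONOTONE_SE_BOUND) | (
                (se == 0) & (beta != 0)
            )
            if np.any(degenerate):
                converged = False
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
        p = np.where(se > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
        return CoxFit(
            gene_ids=tuple(self.gene_ids[i] for i in idx),
            coefficients=beta,
            standard_errors=se,
            wald_z=z,
            wald_p=p,
            log_partial_likelihood=ll,
            converged=converged,
            n_iterations=n_iter,
        )


def fit_cox(
    cohort, gene_ids: Sequence[str], max_iter: int = 100, tol: float = 1e-9
) -> CoxFit:
    """Fit a (multivariate) Cox proportional-hazards model on cohort genes.

    Maximizes the Efron-tie-corrected log partial likelihood by
    Newton-Raphson with step-halving.  Fits whose coefficients exceed
    ``MONOTONE_BETA_BOUND`` in magnitude are flagged ``converged=False``.
    """
    return PreparedCox.from_cohort(cohort).fit(list(gene_ids), max_iter, tol)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve over the distinct event times."""

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1.0 before the first event."""
        i = int(np.searchsorted(self.event_times, t, side="right"))
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def to_dict(self) -> dict:
        return {
            "event_times": [float(t) for t in self.event_times],
            "n_at_risk": [int(v) for v in self.n_at_risk],
            "n_events": [int(v) for v in self.n_events],
            "survival": [float(s) for s in self.survival],
        }


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator; censored subjects shrink risk sets only."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if events.sum() == 0:
        raise ValueError("no events; Kaplan-Meier curve is degenerate")
    order = np.argsort(times, kind="stable")
    t_s, e_s = times[order], events[order]
    evt = np.unique(t_s[e_s == 1])
    n_at_risk = times.size - np.searchsorted(t_s, evt, side="left")
    death_times_sorted = np.sort(times[events == 1])
    n_events = np.searchsorted(death_times_sorted, evt, side="right") - np.searchsorted(
        death_times_sorted, evt, side="left"
    )
    survival = np.cumprod(1.0 - n_events / n_at_risk)
    return KMCurve(
        event_times=evt,
        n_at_risk=n_at_risk.astype(int),
        n_events=n_events.astype(int),
        survival=survival,
    )


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "chi_square": float(self.chi_square),
            "degrees_of_freedom": int(self.degrees_of_freedom),
            "p_value": float(self.p_value),
        }


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test.

    At each pooled event time, compares observed deaths in group A with the
    hypergeometric expectation given the pooled risk set; the squared summed
    difference over the summed variance is chi-square with 1 df.
    """
    ta = np.sort(np.asarray(times_a, dtype=float))
    tb = np.sort(np.asarray(times_b, dtype=float))
    ea = np.asarray(events_a, dtype=float)
    eb = np.asarray(events_b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")

    da_times = np.sort(np.asarray(times_a, dtype=float)[ea == 1])
    db_times = np.sort(np.asarray(times_b, dtype=float)[eb == 1])
    evt = np.unique(np.concatenate([da_times, db_times]))

    na = ta.size - np.searchsorted(ta, evt, side="left")
    nb = tb.size - np.searchsorted(tb, evt, side="left")
    n = na + nb
    dA = np.searchsorted(da_times, evt, side="right") - np.searchsorted(
        da_times, evt, side="left"
    )
    dB = np.searchsorted(db_times, evt, side="right") - np.searchsorted(
        db_times, evt, side="left"
    )
    d = dA + dB

    expected = d * na / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n > 1, d * (na / n) * (nb / n) * (n - d) / np.maximum(n - 1, 1), 0.0
        )
    v_sum = float(var.sum())
    if v_sum <= 0:
        warnings.warn("log-rank variance is zero; returning P = 1", stacklevel=2)
        return LogRankResult(chi_square=0.0, degrees_of_freedom=1, p_value=1.0)
    chi2 = float((dA.sum() - expected.sum()) ** 2 / v_sum)
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(chi_square=chi2, degrees_of_freedom=1, p_value=p)


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    comparable_pairs: int
    concordant: float
    standard_error: float
    ci_low: float
    ci_high: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "c_index": float(self.c_index),
            "comparable_pairs": int(self.comparable_pairs),
            "concordant": float(self.concordant),
            "standard_error": float(self.standard_error),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "p_value": float(self.p_value),
        }


def concordance_index(times, events, risk_scores) -> ConcordanceResult:
    """Harrell's C over comparable pairs.

    Pair (i, j) is comparable iff t_i < t_j and subject i died; tied risk
    scores count 0.5; tied event times with both deaths are not comparable.
    The standard error is a Noether-type normal approximation,
    sqrt(c(1-c)/pairs); the P-value tests c = 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    s = np.asarray(risk_scores, dtype=float)
    if not (t.shape == e.shape == s.shape):
        raise ValueError("times, events and risk_scores must share length")
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs (all times tied or no events)")
    si, sj = s[:, None], s[None, :]
    credit = np.where(si > sj, 1.0, np.where(si == sj, 0.5, 0.0))
    concordant = float(credit[comparable].sum())
    c = concordant / n_pairs
    se = float(np.sqrt(max(c * (1.0 - c), 0.0) / n_pairs))
    if se > 0:
        z = (c - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 1.0 if c == 0.5 else 0.0
    ci_low = float(np.clip(c - 1.96 * se, 0.0, 1.0))
    ci_high = float(np.clip(c + 1.96 * se, 0.0, 1.0))
    return ConcordanceResult(
        c_index=c,
        comparable_pairs=n_pairs,
        concordant=concordant,
        standard_error=se,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# ROC-AUC (Mann-Whitney with DeLong variance)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_positive: int
    n_negative: int

    def to_dict(self) -> dict:
        return {
            "auc": float(self.auc),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "p_value": float(self.p_value),
            "n_positive": int(self.n_positive),
            "n_negative": int(self.n_negative),
        }


def mann_whitney_auc(labels, scores) -> float:
    """AUC via the rank formulation of the Mann-Whitney U statistic.

    Ties receive half credit.  This is the fast path used inside the
    exhaustive search; :func:`roc_auc` reports the identical value.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    m = int(labels.sum())
    n = labels.size - m
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores, method="average")
    u = float(ranks[labels == 1].sum()) - m * (m + 1) / 2.0
    return u / (m * n)


def roc_auc(labels, scores) -> ROCResult:
    """Binary ROC-AUC with DeLong 95% CI and a test of AUC = 0.5.

    The point estimate is the Mann-Whitney probability that a positive
    (death) outscores a negative (survivor), ties counted 0.5; the variance
    comes from the DeLong placement decomposition.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must share length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    auc = mann_whitney_auc(labels, scores)

    psi = np.where(pos[:, None] > neg[None, :], 1.0, 0.0)
    psi[pos[:, None] == neg[None, :]] = 0.5
    v10 = psi.mean(axis=1)  # placements of positives
    v01 = psi.mean(axis=0)  # placements of negatives
    var = 0.0
    if m > 1:
        var += float(np.var(v10, ddof=1)) / m
    if n > 1:
        var += float(np.var(v01, ddof=1)) / n
    se = float(np.sqrt(var))
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return ROCResult(
        auc=float(auc),
        ci_low=float(np.clip(auc - 1.96 * se, 0.0, 1.0)),
        ci_high=float(np.clip(auc + 1.96 * se, 0.0, 1.0)),
        p_value=p,
        n_positive=m,
        n_negative=n,
    )
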