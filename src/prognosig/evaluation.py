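"""Applying a fitted signature to a cohort.

Median-split risk stratification, Kaplan-Meier curves and the log-rank test
between risk groups, ROC-AUC against vital status, Harrell's C against
survival, mean observed survival per group, clinical-subgroup re-evaluation,
cross-platform projection when some signature genes are absent, and the
Pearson coexpression screen around the signature genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionMatrix, SurvivalCohort
from .search import SignatureModel, risk_score
from .survival import (
    ConcordanceResult,
    KMCurve,
    LogRankResult,
    ROCResult,
    concordance_index,
    km_estimate,
    logrank_test,
    roc_auc,
)

__all__ = [
    "StratifiedCohort",
    "EvaluationReport",
    "CoexpressionHit",
    "ProjectionResult",
    "stratify_median",
    "project_signature",
    "evaluate_model",
    "subgroup_evaluate",
    "coexpression_screen",
]


@dataclass(frozen=True)
class StratifiedCohort:
    """Median-split risk groups.

    Samples are sorted by (score, sample ID); the lower half (plus the odd
    extra sample) is low risk.  ``threshold`` is the lowest high-risk score.
    """

    low_risk: list[str]
    high_risk: list[str]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "low_risk": list(self.low_risk),
            "high_risk": list(self.high_risk),
            "threshold": float(self.threshold),
        }


@dataclass(frozen=True)
class ProjectionResult:
    """Risk scores computed from the model genes available on a platform."""

    scores: pd.Series
    genes_used: list[str]
    genes_missing: list[str]


@dataclass(frozen=True)
class EvaluationReport:
    """Everything the pipeline reports about one model on one cohort."""

    km_low: KMCurve
    km_high: KMCurve
    logrank: LogRankResult
    auc: ROCResult
    concordance: ConcordanceResult
    mean_survival_low: float
    mean_survival_high: float
    genes_used: list[str]
    genes_missing: list[str]
    stratification: StratifiedCohort

    def to_dict(self) -> dict:
        return {
            "km_low": self.km_low.to_dict(),
            "km_high": self.km_high.to_dict(),
            "logrank": self.logrank.to_dict(),
            "auc": self.auc.to_dict(),
            "concordance": self.concordance.to_dict(),
            "mean_survival_low": float(self.mean_survival_low),
            "mean_survival_high": float(self.mean_survival_high),
            "genes_used": list(self.genes_used),
            "genes_missing": list(self.genes_missing),
            "stratification": self.stratification.to_dict(),
        }


@dataclass(frozen=True)
class CoexpressionHit:
    gene_id: str
    partner_marker: str
    pcc: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "partner_marker": self.partner_marker,
            "pcc": float(self.pcc),
            "p_value": float(self.p_value),
        }


def stratify_median(scores: pd.Series) -> StratifiedCohort:
    """Split samples evenly at the score median.

    Deterministic: sort by (score, sample ID), low half first; with odd n
    the extra sample joins the low-risk group.  Identical scores everywhere
    cannot be stratified and raise.
    """
    if len(scores) < 2:
        raise ValueError("need at least two samples to stratify")
    if scores.nunique() == 1:
        raise ValueError("all risk scores identical; no meaningful stratification")
    order = sorted(zip(scores.to_numpy(), scores.index.astype(str)))
    n_low = math.ceil(len(order) / 2)
    low = [sid for _, sid in order[:n_low]]
    high = [sid for _, sid in order[n_low:]]
    return StratifiedCohort(low_risk=low, high_risk=high, threshold=float(order[n_low][0]))


def project_signature(
    model: SignatureModel, expression: ExpressionMatrix
) -> ProjectionResult:
    """Score a platform that may lack signature genes.

    Available terms keep their original coefficients; missing terms
    contribute 0 (the model is reused, not refitted).  At least one model
    gene must be present.
    """
    present = [g for g in model.gene_ids if g in expression.data.index]
    missing = [g for g in model.gene_ids if g not in expression.data.index]
    if not present:
        raise KeyError("none of the model genes are present in the expression matrix")
    coef = [c for g, c in zip(model.gene_ids, model.coefficients) if g in set(present)]
    sub = expression.data.loc[present].to_numpy()
    scores = np.asarray(coef, dtype=float) @ sub
    return ProjectionResult(
        scores=pd.Series(scores, index=expression.sample_ids, name="risk_score"),
        genes_used=present,
        genes_missing=missing,
    )


def evaluate_model(model: SignatureModel, cohort: SurvivalCohort) -> EvaluationReport:
    """Full evaluation of a signature on one cohort.

    Risk scores (projected if genes are missing), median-split groups, KM
    per group, log-rank between groups, AUC versus vital status, Harrell's
    C versus survival, and observed mean follow-up time per group.
    """
    projection = project_signature(model, cohort.expression)
    scores = projection.scores
    strata = stratify_median(scores)

    clin = cohort.clinical
    t_low = clin.loc[strata.low_risk, "time_days"].to_numpy(dtype=float)
    e_low = clin.loc[strata.low_risk, "event"].to_numpy(dtype=float)
    t_high = clin.loc[strata.high_risk, "time_days"].to_numpy(dtype=float)
    e_high = clin.loc[strata.high_risk, "event"].to_numpy(dtype=float)

    return EvaluationReport(
        km_low=km_estimate(t_low, e_low),
        km_high=km_estimate(t_high, e_high),
        logrank=logrank_test(t_low, e_low, t_high, e_high),
        auc=roc_auc(cohort.events, scores.to_numpy()),
        concordance=concordance_index(cohort.times, cohort.events, scores.to_numpy()),
        mean_survival_low=float(t_low.mean()),
        mean_survival_high=float(t_high.mean()),
        genes_used=projection.genes_used,
        genes_missing=projection.genes_missing,
        stratification=strata,
    )


def subgroup_evaluate(
    model: SignatureModel,
    cohort: SurvivalCohort,
    factor: str,
    min_n: int = 10,
    merge: dict[str, str] | None = None,
) -> dict[str, EvaluationReport | None]:
    """Re-evaluate the model inside each level of a clinical factor.

    ``factor`` is one of gender/stage/grade; ``merge`` optionally relabels
    sparse levels (e.g. {"IV": "III+IV", "III": "III+IV"}).  Unknown-level
    samples are excluded.  Levels smaller than ``min_n``, or without at
    least one event in each risk group, are reported as None (skipped).
    """
    if factor not in ("gender", "stage", "grade"):
        raise ValueError("factor must be one of gender, stage, grade")
    labels = cohort.clinical[factor].astype(str)
    if merge:
        labels = labels.map(lambda lv: merge.get(lv, lv))
    reports: dict[str, EvaluationReport | None] = {}
    for level in sorted(labels.unique()):
        if level == "unknown":
            continue
        ids = list(labels.index[labels == level])
        if len(ids) < min_n:
            reports[level] = None
            continue
        try:
            sub = cohort.subset_samples(ids)
            report = evaluate_model(model, sub)
        except (ValueError, KeyError):
            reports[level] = None
            continue
        low_events = sub.clinical.loc[report.stratification.low_risk, "event"].sum()
        high_events = sub.clinical.loc[report.stratification.high_risk, "event"].sum()
        reports[level] = report if low_events >= 1 and high_events >= 1 else None
    if not any(r is not None for r in reports.values()):
        warnings.warn(f"no evaluable level for factor {factor!r}", stacklevel=2)
    return reports


def coexpression_screen(
    cohort: SurvivalCohort,
    marker_genes: list[str],
    pcc_threshold: float = 0.6,
    p_threshold: float = 0.01,
    use_absolute: bool = False,
) -> list[CoexpressionHit]:
    """Pearson coexpression screen around the signature genes.

    For every non-marker gene and every marker, computes Pearson's r and
    its two-sided t-distribution P; retains pairs with r > pcc_threshold
    (|r| if ``use_absolute``) and P < p_threshold.  Zero-variance genes are
    skipped with a warning.
    """
    expr = cohort.expression.data
    missing = [m for m in marker_genes if m not in expr.index]
    if missing:
        raise KeyError(f"marker genes not in cohort: {missing}")
    n = expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation P-value")
    values = expr.to_numpy()
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    zero_var = norms == 0
    if zero_var.any():
        warnings.warn(
            f"skipping {int(zero_var.sum())} zero-variance genes in coexpression screen",
            stacklevel=2,
        )
    gene_index = {g: i for i, g in enumerate(expr.index)}
    hits: list[CoexpressionHit] = []
    marker_set = set(marker_genes)
    for marker in marker_genes:
        mi = gene_index[marker]
        if zero_var[mi]:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            r = centered @ centered[mi] / (norms * norms[mi])
        r = np.clip(r, -1.0, 1.0)
        stat = np.abs(r) if use_absolute else r
        # two-sided P from t = r * sqrt((n-2)/(1-r^2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
        pvals = 2.0 * stats.t.sf(np.abs(tval), df=n - 2)
        for g in expr.index:
            gi = gene_index[g]
            if g in marker_set or zero_var[gi]:
                continue
            if stat[gi] > pcc_threshold and pvals[gi] < p_threshold:
                hits.append(
                    CoexpressionHit(
                        gene_id=g,
                        partner_marker=marker,
                        pcc=float(r[gi]),
                        p_value=float(pvals[gi]),
                    )
                )
    return hits
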