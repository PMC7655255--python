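"""Exhaustive AUC-maximizing search over small gene combinations.

The discovery procedure: screen every gene with a univariate Cox Wald test,
then traverse ALL combinations of 1..k surviving candidates, fit each by
multivariate Cox on the training cohort, score the resulting risk scores
against end-of-follow-up vital status by ROC-AUC, and keep the maximum.

The traversal is deterministic (lexicographic in candidate order), supports
contiguous chunking so parallel workers or resumable batch jobs reproduce
the single-process result bit for bit, and skips non-convergent
(separation-degenerate) fits rather than letting them poison the argmax.

Tie-break for the argmax: higher AUC, then fewer genes, then the
lexicographically smallest sorted gene-ID tuple — so the winner does not
depend on worker count, chunk boundaries, or candidate input order.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cohort_io import ExpressionMatrix, SurvivalCohort
from .survival import CoxFit, PreparedCox, mann_whitney_auc

__all__ = [
    "ScreenResult",
    "SignatureModel",
    "SearchResult",
    "univariate_screen",
    "enumerate_combinations",
    "count_combinations",
    "chunk_bounds",
    "evaluate_combination",
    "exhaustive_search",
    "search_chunk",
    "merge_search_results",
    "risk_score",
]


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenResult:
    """Univariate Cox screen outcome.

    ``per_gene`` maps each retained candidate to its (coefficient, Wald P);
    candidates keep the cohort's stable gene order.
    """

    candidate_gene_ids: list[str]
    per_gene: dict[str, tuple[float, float]]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "candidate_gene_ids": list(self.candidate_gene_ids),
            "per_gene": {
                g: {"coefficient": float(c), "wald_p": float(p)}
                for g, (c, p) in self.per_gene.items()
            },
            "threshold": float(self.threshold),
        }


def univariate_screen(
    cohort: SurvivalCohort, p_threshold: float = 0.001
) -> ScreenResult:
    """One single-gene Cox fit per gene; keep converged fits with P below
    the threshold, in stable input order."""
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError("p_threshold must be in (0, 1]")
    prepared = PreparedCox.from_cohort(cohort)
    candidates: list[str] = []
    per_gene: dict[str, tuple[float, float]] = {}
    for i, gene in enumerate(cohort.gene_ids):
        fit = prepared.fit([i])
        if fit.converged and fit.wald_p[0] < p_threshold:
            candidates.append(gene)
            per_gene[gene] = (float(fit.coefficients[0]), float(fit.wald_p[0]))
    if not candidates:
        raise ValueError(
            f"no gene passed the P < {p_threshold} screen; loosen the threshold"
        )
    return ScreenResult(
        candidate_gene_ids=candidates, per_gene=per_gene, threshold=p_threshold
    )


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def count_combinations(n_candidates: int, max_size: int) -> int:
    """Number of subsets of size 1..max_size from ``n_candidates`` genes."""
    max_size = min(max_size, n_candidates)
    return sum(math.comb(n_candidates, j) for j in range(1, max_size + 1))


def enumerate_combinations(
    candidates: Sequence[str], max_size: int
) -> Iterator[tuple[str, ...]]:
    """Yield every 1..max_size combination exactly once.

    Order is deterministic: sizes ascending, then lexicographic by candidate
    position — the contract that makes chunked/parallel traversal exact.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if max_size > len(candidates):
        warnings.warn(
            f"max_size {max_size} exceeds candidate count {len(candidates)}; capping",
            stacklevel=2,
        )
        max_size = len(candidates)
    for size in range(1, max_size + 1):
        yield from itertools.combinations(candidates, size)


def chunk_bounds(total: int, n_chunks: int) -> list[tuple[int, int]]:
    """Split [0, total) into ``n_chunks`` contiguous near-equal ranges."""
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    edges = np.linspace(0, total, n_chunks + 1).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_chunks)]


# ---------------------------------------------------------------------------
# Models and evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureModel:
    """Ordered gene IDs with Cox coefficients; the risk score is their
    linear combination, score_i = sum_g coefficient_g * E_{g,i}."""

    gene_ids: tuple[str, ...]
    coefficients: tuple[float, ...]
    training_auc: float | None = None

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.coefficients):
            raise ValueError("gene_ids and coefficients must align")
        if not all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.gene_ids),
            "coefficients": [float(c) for c in self.coefficients],
            "training_auc": None
            if self.training_auc is None
            else float(self.training_auc),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        return cls(
            gene_ids=tuple(d["gene_ids"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            training_auc=d.get("training_auc"),
        )


@dataclass(frozen=True)
class SearchResult:
    """Best signature under the AUC objective plus enumeration bookkeeping."""

    best: SignatureModel
    n_enumerated: int
    n_skipped_nonconverged: int
    per_size_best: dict[int, SignatureModel]

    def to_dict(self) -> dict:
        return {
            "best": self.best.to_dict(),
            "n_enumerated": int(self.n_enumerated),
            "n_skipped_nonconverged": int(self.n_skipped_nonconverged),
            "per_size_best": {
                str(k): m.to_dict() for k, m in sorted(self.per_size_best.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SearchResult":
        return cls(
            best=SignatureModel.from_dict(d["best"]),
            n_enumerated=int(d["n_enumerated"]),
            n_skipped_nonconverged=int(d["n_skipped_nonconverged"]),
            per_size_best={
                int(k): SignatureModel.from_dict(m)
                for k, m in d["per_size_best"].items()
            },
        )


def risk_score(model: SignatureModel, expression: ExpressionMatrix) -> pd.Series:
    """Per-sample risk score: the coefficient-weighted sum of expression.

    Every model gene must be present; for platforms lacking genes use
    ``model_evaluation.project_signature`` instead.
    """
    missing = [g for g in model.gene_ids if g not in expression.data.index]
    if missing:
        raise KeyError(
            f"genes {missing} absent from expression matrix; use "
            "project_signature for cross-platform cohorts"
        )
    sub = expression.data.loc[list(model.gene_ids)].to_numpy()
    scores = np.asarray(model.coefficients, dtype=float) @ sub
    return pd.Series(scores, index=expression.sample_ids, name="risk_score")


def evaluate_combination(
    cohort: SurvivalCohort, gene_ids: Sequence[str]
) -> tuple[CoxFit, float] | None:
    """Fit one combination on the cohort and score its training AUC.

    Returns None (a skip marker) when the multivariate fit does not
    converge, e.g. under monotone likelihood.
    """
    prepared = PreparedCox.from_cohort(cohort)
    return _evaluate_prepared(prepared, cohort.events, list(gene_ids))


def _evaluate_prepared(
    prepared: PreparedCox, labels: np.ndarray, genes: Sequence
) -> tuple[CoxFit, float] | None:
    fit = prepared.fit(genes)
    if not fit.converged or not np.all(np.isfinite(fit.coefficients)):
        return None
    # risk scores in sorted sample order; AUC is order-invariant
    idx = [prepared._index[g] if isinstance(g, str) else g for g in genes]
    scores = prepared.X_sorted[:, idx] @ fit.coefficients
    auc = mann_whitney_auc(prepared.data.event, scores)
    return fit, float(auc)


def _better(key_a: tuple, key_b: tuple | None) -> bool:
    return key_b is None or key_a < key_b


def _model_key(auc: float, genes: tuple[str, ...]) -> tuple:
    return (-auc, len(genes), tuple(sorted(genes)))


def search_chunk(
    cohort: SurvivalCohort,
    candidates: Sequence[str],
    max_size: int,
    start: int,
    stop: int,
) -> dict:
    """Evaluate combinations with enumeration index in [start, stop).

    Returns a mergeable partial result (per-size bests + counters); chunk
    boundaries never affect the merged argmax.
    """
    prepared = PreparedCox.from_cohort(cohort)
    labels = cohort.events
    n_eval = 0
    n_skip = 0
    best_by_size: dict[int, tuple[tuple, SignatureModel]] = {}
    combos = itertools.islice(
        enumerate_combinations(list(candidates), max_size), start, stop
    )
    for genes in combos:
        n_eval += 1
        result = _evaluate_prepared(prepared, labels, genes)
        if result is None:
            n_skip += 1
            continue
        fit, auc = result
        key = _model_key(auc, genes)
        size = len(genes)
        if size not in best_by_size or _better(key, best_by_size[size][0]):
            model = SignatureModel(
                gene_ids=tuple(genes),
                coefficients=tuple(float(c) for c in fit.coefficients),
                training_auc=auc,
            )
            best_by_size[size] = (key, model)
    return {
        "n_evaluated": n_eval,
        "n_skipped_nonconverged": n_skip,
        "best_by_size": best_by_size,
    }


def merge_search_results(partials: Iterable[dict], n_enumerated: int) -> SearchResult:
    """Merge chunk partials into one SearchResult (deterministic)."""
    n_eval = 0
    n_skip = 0
    best_by_size: dict[int, tuple[tuple, SignatureModel]] = {}
    for part in partials:
        n_eval += part["n_evaluated"]
        n_skip += part["n_skipped_nonconverged"]
        for size, (key, model) in part["best_by_size"].items():
            if size not in best_by_size or _better(key, best_by_size[size][0]):
                best_by_size[size] = (key, model)
    if n_eval != n_enumerated:
        raise ValueError(
            f"chunks covered {n_eval} combinations, expected {n_enumerated}"
        )
    if not best_by_size:
        raise ValueError("every combination was skipped as non-convergent")
    global_key = None
    best = None
    for size in sorted(best_by_size):
        key, model = best_by_size[size]
        if _better(key, global_key):
            global_key, best = key, model
    return SearchResult(
        best=best,
        n_enumerated=n_enumerated,
        n_skipped_nonconverged=n_skip,
        per_size_best={s: m for s, (_, m) in sorted(best_by_size.items())},
    )


def exhaustive_search(
    cohort: SurvivalCohort,
    screen: ScreenResult,
    max_size: int = 3,
    workers: int = 1,
    n_chunks: int | None = None,
) -> SearchResult:
    """Traverse all 1..max_size combinations of screened candidates.

    The result is the argmax by (training AUC, then fewer genes, then
    lexicographic gene IDs) and is identical for any ``workers`` or chunking.
    """
    candidates = list(screen.candidate_gene_ids)
    if not candidates:
        raise ValueError("screen produced no candidates")
    max_size = min(max_size, len(candidates))
    total = count_combinations(len(candidates), max_size)
    bounds = chunk_bounds(total, n_chunks or max(workers, 1))
    if workers > 1:
        partials = Parallel(n_jobs=workers)(
            delayed(search_chunk)(cohort, candidates, max_size, lo, hi)
            for lo, hi in bounds
        )
    else:
        partials = [
            search_chunk(cohort, candidates, max_size, lo, hi) for lo, hi in bounds
        ]
    return merge_search_results(partials, total)
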