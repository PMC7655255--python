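"""Synthetic survival cohorts with a planted expression signature.

The generator reproduces the statistical structure the discovery pipeline
assumes: many null genes on a log2 expression scale, a small planted set
whose linear combination drives hazard under a proportional-hazards model,
exponential event times, and tunable right censoring.  It deliberately does
NOT mimic any real dataset's marginal distributions or gene-gene correlation
structure — it exists so every downstream stage is testable without
external data.

Model
-----
Expression: x_{g,i} = max(0, Normal(location, scale)), with a
``zero_inflation`` fraction of entries forced to exactly 0 (mimicking
undetected transcripts, and giving the prevalence filter something to do).

Hazard: h_i = baseline_hazard * exp(eta_i - mean(eta)) with
eta_i = sum_g beta_g x_{g,i} over the planted genes.  Centring the linear
predictor is absorbed into the baseline hazard (Cox inference is invariant
to it) and keeps ``baseline_hazard`` the hazard of a typical sample.

Censoring: an independent exponential censoring time whose rate c solves
mean_i[c / (c + h_i)] = censor_rate exactly (1-d root solve), so the
expected censored fraction matches the target even under planted signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort_io import (
    ExpressionMatrix,
    SurvivalCohort,
    ValidationError,
)

__all__ = ["SyntheticConfig", "generate_cohort", "make_cross_platform_view"]

# Clinical-covariate frequencies of a typical HCC RNA-seq cohort; the
# covariates are independent of survival (subgroup machinery only needs the
# labels, not a confounded signal).
_GENDER_P = {"male": 0.67, "female": 0.33}
_STAGE_P = {"I": 0.46, "II": 0.23, "III": 0.23, "IV": 0.015, "unknown": 0.065}
_GRADE_P = {"G1": 0.15, "G2": 0.48, "G3": 0.32, "G4": 0.035, "unknown": 0.015}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    Defaults are the package's reference study conditions: a 370-sample
    cohort on a days time scale with ~65% censoring, log2-scale expression
    centred at 3.0 with SD 1.5, 20% zero-inflation, and a 3-gene planted
    signature carrying the published model's coefficients.
    """

    n_samples: int = 370
    n_genes: int = 500
    planted_genes: tuple[int, ...] = (0, 1, 2)
    planted_betas: tuple[float, ...] = (0.7675, 0.1726, -0.2466)
    baseline_hazard: float = 1.0 / 800.0  # per day
    censor_rate: float = 0.65
    expression_location: float = 3.0
    expression_scale: float = 1.5
    zero_inflation: float = 0.2
    round_to_days: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValidationError("need n_samples >= 2 and n_genes >= 1")
        if len(set(self.planted_genes)) != len(self.planted_genes):
            raise ValidationError("planted_genes indices must be distinct")
        if any(g < 0 or g >= self.n_genes for g in self.planted_genes):
            raise ValidationError("planted_genes indices must be < n_genes")
        if len(self.planted_betas) != len(self.planted_genes):
            raise ValidationError("planted_betas must align with planted_genes")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValidationError("censor_rate must be in [0, 1)")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ValidationError("zero_inflation must be in [0, 1)")
        if self.baseline_hazard <= 0 or self.expression_scale <= 0:
            raise ValidationError("baseline_hazard and expression_scale must be > 0")


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def _sample_id(i: int) -> str:
    return f"S{i:04d}"


def _censoring_rate_for(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i[c/(c+h_i)] = target."""

    def deficit(log_c: float) -> float:
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - target

    lo = float(np.log(hazards.min())) - 30.0
    hi = float(np.log(hazards.max())) + 30.0
    return float(np.exp(brentq(deficit, lo, hi, xtol=1e-12)))


def generate_cohort(config: SyntheticConfig) -> SurvivalCohort:
    """Draw one cohort under ``config``; bit-identical for a given seed."""
    rng = np.random.default_rng(config.seed)
    g, n = config.n_genes, config.n_samples

    expr = config.expression_location + config.expression_scale * rng.standard_normal(
        (g, n)
    )
    np.maximum(expr, 0.0, out=expr)
    if config.zero_inflation > 0:
        expr[rng.random((g, n)) < config.zero_inflation] = 0.0

    planted = np.asarray(config.planted_genes, dtype=int)
    betas = np.asarray(config.planted_betas, dtype=float)
    if planted.size and not np.any(betas != 0):
        warnings.warn("all planted coefficients are zero: cohort carries no signal",
                      stacklevel=2)
    eta = betas @ expr[planted] if planted.size else np.zeros(n)
    eta = eta - eta.mean()
    hazards = config.baseline_hazard * np.exp(eta)

    event_times = rng.exponential(1.0 / hazards)
    if config.censor_rate > 0:
        c = _censoring_rate_for(hazards, config.censor_rate)
        censor_times = rng.exponential(1.0 / c, size=n)
        observed = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    else:
        observed = event_times
        events = np.ones(n, dtype=int)
    if config.round_to_days:
        observed = np.maximum(np.round(observed), 1.0)

    gender = rng.choice(list(_GENDER_P), size=n, p=list(_GENDER_P.values()))
    stage = rng.choice(list(_STAGE_P), size=n, p=list(_STAGE_P.values()))
    grade = rng.choice(list(_GRADE_P), size=n, p=list(_GRADE_P.values()))
    age = np.round(np.clip(rng.normal(60.0, 10.0, size=n), 18.0, 95.0), 1)

    sample_ids = [_sample_id(i) for i in range(n)]
    clinical = pd.DataFrame(
        {
            "time_days": observed,
            "event": events,
            "gender": gender,
            "stage": stage,
            "grade": grade,
            "age": age,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=[_gene_id(i) for i in range(g)], columns=sample_ids)
    )
    return SurvivalCohort(expression=matrix, clinical=clinical)


def planted_gene_ids(config: SyntheticConfig) -> list[str]:
    """Gene IDs of the planted signature under ``config``'s naming."""
    return [_gene_id(i) for i in config.planted_genes]


def make_cross_platform_view(
    cohort: SurvivalCohort,
    missing_genes: list[str],
    shift: float = 0.0,
    scale: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> SurvivalCohort:
    """Emulate the same patients measured on another platform.

    Listed genes are removed (platforms rarely share a full feature space);
    the remaining values are affinely distorted, x -> scale*x + shift plus
    seeded Gaussian noise, then clipped at 0 to stay on the log2(x+1) >= 0
    domain.  Clinical records are untouched.
    """
    genes = cohort.gene_ids
    missing_set = set(missing_genes)
    unknown = missing_set - set(genes)
    if unknown:
        raise ValidationError(f"missing_genes not in cohort: {sorted(unknown)}")
    kept = [g for g in genes if g not in missing_set]
    if not kept:
        raise ValidationError("cross-platform view would remove every gene")
    rng = np.random.default_rng(seed)
    values = cohort.expression.data.loc[kept].to_numpy() * scale + shift
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=kept, columns=cohort.sample_ids)
    )
    return SurvivalCohort(expression=matrix, clinical=cohort.clinical)
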