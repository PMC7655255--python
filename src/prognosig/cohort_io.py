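"""Reading, validating, normalizing, filtering and splitting expression
cohorts.

Expression arrives as a genes x samples TSV of raw, non-negative abundances
(e.g. FPKM-UQ) which are normalized to log2(x + 1), or pre-logged values via
a flag for data that already live on the log scale (e.g. array platforms).
Clinical tables carry per-sample survival time in days, a 0/1 vital-status
event flag, and the categorical covariates used in subgroup analyses.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "ParseError",
    "ValidationError",
    "ExpressionMatrix",
    "ClinicalRecord",
    "ClinicalReadResult",
    "SurvivalCohort",
    "read_expression",
    "read_clinical",
    "clinical_to_frame",
    "assemble_cohort",
    "filter_low_expression",
    "split_cohort",
    "write_expression",
    "write_clinical",
    "UNKNOWN_TOKEN",
]

logger = logging.getLogger(__name__)

#: Token encoding an unknown categorical/age value in clinical TSVs.
UNKNOWN_TOKEN = "NA"

GENDER_LEVELS = ("male", "female", "unknown")
STAGE_LEVELS = ("I", "II", "III", "IV", "unknown")
GRADE_LEVELS = ("G1", "G2", "G3", "G4", "unknown")

CLINICAL_COLUMNS = ["sample_id", "time_days", "event", "gender", "stage", "grade", "age"]


class CohortError(ValueError):
    """Base class for cohort construction failures."""


class ParseError(CohortError):
    """Malformed input file (non-numeric cell, missing column, ...)."""


class ValidationError(CohortError):
    """Input parsed but violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples grid of log2(x+1)-normalized abundances.

    ``data`` is indexed by gene ID with sample IDs as columns; values are
    finite and >= 0, IDs unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate gene ID: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample ID: {dup!r}")
        values = self.data.to_numpy()
        if values.size and (not np.all(np.isfinite(values)) or np.any(values < 0)):
            raise ValidationError("expression values must be finite and >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's survival and covariate record.

    ``survival_time`` is days (> 0); ``event`` is 1 for observed death and 0
    for censoring; ``age`` is years or NaN when unknown.
    """

    sample_id: str
    survival_time: float
    event: int
    gender: str = "unknown"
    stage: str = "unknown"
    grade: str = "unknown"
    age: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.survival_time > 0):
            raise ValidationError(
                f"sample {self.sample_id!r}: survival_time must be > 0"
            )
        if self.event not in (0, 1):
            raise ValidationError(f"sample {self.sample_id!r}: event must be 0 or 1")
        if self.gender not in GENDER_LEVELS:
            raise ValidationError(f"sample {self.sample_id!r}: bad gender {self.gender!r}")
        if self.stage not in STAGE_LEVELS:
            raise ValidationError(f"sample {self.sample_id!r}: bad stage {self.stage!r}")
        if self.grade not in GRADE_LEVELS:
            raise ValidationError(f"sample {self.sample_id!r}: bad grade {self.grade!r}")


@dataclass(frozen=True)
class ClinicalReadResult:
    """Parsed clinical records plus the count of rows dropped for missing
    survival information."""

    records: list[ClinicalRecord]
    n_dropped: int


@dataclass(frozen=True)
class SurvivalCohort:
    """Expression joined with clinical records, sample-aligned.

    ``clinical`` is indexed by sample ID in the same order as the expression
    columns, with columns time_days, event, gender, stage, grade, age.
    """

    expression: ExpressionMatrix
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.clinical.index) != self.expression.sample_ids:
            raise ValidationError(
                "clinical sample IDs must match expression samples in order"
            )
        if int(self.clinical["event"].sum()) < 1:
            raise ValidationError("cohort must contain at least one event")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def gene_ids(self) -> list[str]:
        return self.expression.gene_ids

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    @property
    def times(self) -> np.ndarray:
        return self.clinical["time_days"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.clinical["event"].to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "SurvivalCohort":
        ids = list(sample_ids)
        return SurvivalCohort(
            expression=ExpressionMatrix(self.expression.data[ids]),
            clinical=self.clinical.loc[ids],
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "SurvivalCohort":
        return SurvivalCohort(
            expression=ExpressionMatrix(self.expression.data.loc[list(gene_ids)]),
            clinical=self.clinical,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression(path, already_log: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV; normalize to log2(x+1) unless pre-logged.

    The first column holds gene IDs, the header row sample IDs, the body
    numeric non-negative abundances.  Duplicated IDs, negative or
    non-numeric cells raise with the offending row/column named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ParseError(
            f"non-numeric or missing value at gene {gene!r}, sample {sample!r}: "
            f"{df.loc[gene, sample]!r}"
        )
    values = num.astype(float)
    if (values.to_numpy() < 0).any():
        gene = values.index[(values < 0).any(axis=1)][0]
        raise ValidationError(f"negative abundance for gene {gene!r}")
    if not already_log:
        values = np.log2(values + 1.0)
    return ExpressionMatrix(values)


def _parse_gender(token: str) -> str:
    t = token.strip().lower()
    if t in ("male", "m"):
        return "male"
    if t in ("female", "f"):
        return "female"
    if t in ("", UNKNOWN_TOKEN.lower(), "na", "unknown", "other", "others"):
        return "unknown"
    raise ValidationError(f"unrecognized gender token {token!r}")


def _parse_stage(token: str) -> str:
    t = token.strip().upper().removeprefix("STAGE").strip()
    if t in ("I", "II", "III", "IV"):
        return t
    if t in ("", UNKNOWN_TOKEN.upper(), "UNKNOWN", "OTHER", "OTHERS"):
        return "unknown"
    raise ValidationError(f"unrecognized stage token {token!r}")


def _parse_grade(token: str) -> str:
    t = token.strip().upper()
    if t in ("G1", "G2", "G3", "G4"):
        return t
    if t in ("1", "2", "3", "4"):
        return f"G{t}"
    if t in ("", UNKNOWN_TOKEN.upper(), "UNKNOWN", "OTHER", "OTHERS"):
        return "unknown"
    raise ValidationError(f"unrecognized grade token {token!r}")


def read_clinical(path) -> ClinicalReadResult:
    """Read a clinical TSV; drop (and count) rows missing time or event.

    Expected columns: sample_id, time_days, event, gender, stage, grade,
    age; unknown categorical/age values encoded as ``NA``.  A survival time
    <= 0 or an event flag outside {0, 1} is an error rather than a drop.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"clinical table missing columns: {missing_cols}")

    records: list[ClinicalRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        time_tok = str(row["time_days"]).strip()
        event_tok = str(row["event"]).strip()
        if time_tok in ("", UNKNOWN_TOKEN) or event_tok in ("", UNKNOWN_TOKEN):
            n_dropped += 1
            continue
        try:
            time_val = float(time_tok)
        except ValueError as exc:
            raise ParseError(
                f"sample {row['sample_id']!r}: bad survival time {time_tok!r}"
            ) from exc
        if not (time_val > 0):
            raise ValidationError(
                f"sample {row['sample_id']!r}: survival time must be > 0"
            )
        if event_tok not in ("0", "1"):
            raise ValidationError(
                f"sample {row['sample_id']!r}: event must be 0 or 1, got {event_tok!r}"
            )
        age_tok = str(row["age"]).strip()
        age = float("nan") if age_tok in ("", UNKNOWN_TOKEN) else float(age_tok)
        if age == age and age < 0:
            raise ValidationError(f"sample {row['sample_id']!r}: negative age")
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]),
                survival_time=time_val,
                event=int(event_tok),
                gender=_parse_gender(str(row["gender"])),
                stage=_parse_stage(str(row["stage"])),
                grade=_parse_grade(str(row["grade"])),
                age=age,
            )
        )
    if n_dropped:
        logger.info("read_clinical: dropped %d rows missing time/event", n_dropped)
    if not records:
        warnings.warn("clinical table contains zero usable rows", stacklevel=2)
    return ClinicalReadResult(records=records, n_dropped=n_dropped)


def clinical_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    """Convert clinical records to the cohort's canonical DataFrame layout."""
    rows = [
        {
            "sample_id": r.sample_id,
            "time_days": r.survival_time,
            "event": r.event,
            "gender": r.gender,
            "stage": r.stage,
            "grade": r.grade,
            "age": r.age,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
    return frame.set_index("sample_id")


def assemble_cohort(
    expr: ExpressionMatrix, clin: Sequence[ClinicalRecord]
) -> SurvivalCohort:
    """Join expression and clinical records on their common samples.

    Samples present in only one input are dropped (and logged); an empty
    intersection is an error.  Sample order follows the expression matrix.
    """
    clin_frame = clinical_to_frame(clin)
    if clin_frame.index.has_duplicates:
        dup = clin_frame.index[clin_frame.index.duplicated()][0]
        raise ValidationError(f"duplicate clinical sample ID: {dup!r}")
    common = [s for s in expr.sample_ids if s in set(clin_frame.index)]
    if not common:
        raise ValidationError("expression and clinical tables share no samples")
    dropped = (len(expr.sample_ids) - len(common)) + (len(clin_frame) - len(common))
    if dropped:
        logger.info("assemble_cohort: dropped %d unmatched samples", dropped)
    return SurvivalCohort(
        expression=ExpressionMatrix(expr.data[common]),
        clinical=clin_frame.loc[common],
    )


def filter_low_expression(
    cohort: SurvivalCohort, min_nonzero_fraction: float = 0.5
) -> tuple[SurvivalCohort, int]:
    """Keep genes nonzero in at least ``ceil(n * fraction)`` samples.

    With the default fraction 0.5 this is the "nonzero in at least half the
    specimens" prevalence rule.  Returns the filtered cohort and the
    retained-gene count; removing every gene is an error.
    """
    n = cohort.n_samples
    required = math.ceil(n * min_nonzero_fraction)
    nonzero = (cohort.expression.values > 0).sum(axis=1)
    keep = nonzero >= required
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValidationError("prevalence filter removed every gene")
    kept_genes = [g for g, k in zip(cohort.gene_ids, keep) if k]
    return cohort.subset_genes(kept_genes), n_kept


def split_cohort(
    cohort: SurvivalCohort, train_fraction: float, seed: int
) -> tuple[SurvivalCohort, SurvivalCohort]:
    """Simple random train/validation split, reproducible under ``seed``.

    Sizes are round(n * fraction) and the remainder; the two parts partition
    the cohort.  An empty part is an error.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must be in (0, 1)")
    n = cohort.n_samples
    n_train = int(math.floor(n * train_fraction + 0.5))
    if n_train == 0 or n_train == n:
        raise ValidationError("split would leave an empty part")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = np.asarray(cohort.sample_ids, dtype=object)
    train_ids = sorted(ids[perm[:n_train]])
    val_ids = sorted(ids[perm[n_train:]])
    return cohort.subset_samples(train_ids), cohort.subset_samples(val_ids)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write the (log-scale) expression matrix as TSV; read back with
    ``already_log=True``."""
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def write_clinical(clinical: pd.DataFrame, path) -> None:
    """Write a cohort clinical frame as TSV with ``NA`` for unknowns."""
    out = clinical.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep=UNKNOWN_TOKEN)
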