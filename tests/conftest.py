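import numpy as np
import pandas as pd
import pytest

from prognosig.cohort_io import ExpressionMatrix, SurvivalCohort
from prognosig.synthetic import SyntheticConfig, generate_cohort


def make_cohort(times, events, expr=None, gene_ids=None, **clinical_cols):
    """Build a small SurvivalCohort from raw arrays (expression >= 0)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = times.size
    if expr is None:
        expr = np.ones((1, n))
    expr = np.atleast_2d(np.asarray(expr, dtype=float))
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(expr.shape[0])]
    sample_ids = [f"s{i:03d}" for i in range(n)]
    clinical = pd.DataFrame(
        {
            "time_days": times,
            "event": events,
            "gender": clinical_cols.get("gender", ["unknown"] * n),
            "stage": clinical_cols.get("stage", ["unknown"] * n),
            "grade": clinical_cols.get("grade", ["unknown"] * n),
            "age": clinical_cols.get("age", [60.0] * n),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SurvivalCohort(
        expression=ExpressionMatrix(
            pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
        ),
        clinical=clinical,
    )


@pytest.fixture(scope="session")
def signal_cohort():
    """A 400-sample cohort with a strong 3-gene planted signature."""
    cfg = SyntheticConfig(
        n_samples=400,
        n_genes=23,
        planted_genes=(0, 1, 2),
        planted_betas=(1.0, -0.9, 0.8),
        censor_rate=0.3,
        expression_location=3.0,
        expression_scale=1.0,
        zero_inflation=0.0,
        seed=12,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort whose survival is independent of every gene."""
    cfg = SyntheticConfig(
        n_samples=200,
        n_genes=50,
        planted_genes=(),
        planted_betas=(),
        censor_rate=0.3,
        zero_inflation=0.0,
        seed=77,
    )
    return generate_cohort(cfg)
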