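"""Resampling-based comparison of competing prognostic signatures.

Repeatedly draws random 50% (configurable) subsamples of a cohort without
replacement, scores every model on each subsample (through cross-platform
projection, so published models with absent genes still evaluate), records
per-resample AUC and C-index, and compares models pairwise by Welch's
t-test on the AUC vectors.

By default the same subsamples are used for all models (a paired design,
which removes subsample-to-subsample variance from the comparison); an
unpaired mode draws independent subsamples per model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import SurvivalCohort
from .evaluation import project_signature
from .search import SignatureModel
from .survival import concordance_index, mann_whitney_auc

__all__ = ["ComparisonReport", "resample_compare", "read_models_tsv", "write_models_tsv"]


@dataclass(frozen=True)
class ComparisonReport:
    """Per-model resample distributions and pairwise t-test P-values."""

    model_names: list[str]
    auc_samples: pd.DataFrame  # R x models
    c_samples: pd.DataFrame  # R x models
    mean_auc: dict[str, float]
    mean_c: dict[str, float]
    pairwise_p: pd.DataFrame  # models x models, symmetric, unit diagonal
    seed: int
    n_redrawn: int
    degenerate_pairs: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "mean_auc": {k: float(v) for k, v in self.mean_auc.items()},
            "mean_c": {k: float(v) for k, v in self.mean_c.items()},
            "pairwise_p": {
                a: {b: float(self.pairwise_p.loc[a, b]) for b in self.model_names}
                for a in self.model_names
            },
            "seed": int(self.seed),
            "repetitions": int(len(self.auc_samples)),
            "n_redrawn": int(self.n_redrawn),
            "degenerate_pairs": [list(p) for p in self.degenerate_pairs],
        }


def _draw_subsample(
    rng: np.random.Generator, events: np.ndarray, size: int, max_retries: int = 100
) -> tuple[np.ndarray, int]:
    """Without-replacement subsample containing both outcome classes."""
    n = events.size
    retries = 0
    while True:
        idx = rng.choice(n, size=size, replace=False)
        sub = events[idx]
        if 0 < sub.sum() < size:
            return idx, retries
        retries += 1
        if retries > max_retries:
            raise ValueError(
                "could not draw a subsample containing both outcome classes"
            )


def resample_compare(
    cohort: SurvivalCohort,
    models: Mapping[str, SignatureModel],
    repetitions: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    paired: bool = True,
) -> ComparisonReport:
    """Random-subsampling model comparison.

    For each of ``repetitions`` draws of floor(fraction * n) samples,
    computes every model's AUC (score vs vital status) and Harrell's C,
    then runs pairwise two-sided Welch t-tests on the AUC vectors.
    Identical AUC vectors yield P = 1 by convention and are flagged.
    """
    if not models:
        raise ValueError("at least one model is required")
    if repetitions < 2:
        raise ValueError("repetitions must be >= 2")
    if repetitions < 10:
        warnings.warn(
            f"only {repetitions} resamples; comparison will be noisy", stacklevel=2
        )
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    size = int(np.floor(fraction * cohort.n_samples))
    if size < 4:
        raise ValueError("subsample size too small")

    names = list(models)
    times = cohort.times
    events = cohort.events
    # full-cohort scores once per model; subsamples just index into them
    full_scores = {
        name: project_signature(model, cohort.expression).scores.to_numpy()
        for name, model in models.items()
    }

    auc = np.empty((repetitions, len(names)))
    cidx = np.empty((repetitions, len(names)))
    n_redrawn = 0
    if paired:
        rng = np.random.default_rng(seed)
        for r in range(repetitions):
            idx, retries = _draw_subsample(rng, events, size)
            n_redrawn += retries
            for j, name in enumerate(names):
                s = full_scores[name][idx]
                auc[r, j] = mann_whitney_auc(events[idx], s)
                cidx[r, j] = concordance_index(times[idx], events[idx], s).c_index
    else:
        for j, name in enumerate(names):
            rng = np.random.default_rng(np.random.SeedSequence([seed, j]))
            for r in range(repetitions):
                idx, retries = _draw_subsample(rng, events, size)
                n_redrawn += retries
                s = full_scores[name][idx]
                auc[r, j] = mann_whitney_auc(events[idx], s)
                cidx[r, j] = concordance_index(times[idx], events[idx], s).c_index

    auc_df = pd.DataFrame(auc, columns=names)
    c_df = pd.DataFrame(cidx, columns=names)
    pairwise = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    degenerate: list[tuple[str, str]] = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            x, y = auc[:, i], auc[:, j]
            if np.array_equal(x, y) or (x.std(ddof=1) == 0 and y.std(ddof=1) == 0):
                p = 1.0
                degenerate.append((a, b))
            else:
                p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
                if not np.isfinite(p):
                    p = 1.0
                    degenerate.append((a, b))
            pairwise.loc[a, b] = pairwise.loc[b, a] = p
    return ComparisonReport(
        model_names=names,
        auc_samples=auc_df,
        c_samples=c_df,
        mean_auc={n: float(auc_df[n].mean()) for n in names},
        mean_c={n: float(c_df[n].mean()) for n in names},
        pairwise_p=pairwise,
        seed=seed,
        n_redrawn=n_redrawn,
        degenerate_pairs=degenerate,
    )


def read_models_tsv(path) -> dict[str, SignatureModel]:
    """Read published comparator models from a TSV with columns
    model_name, gene_id, coefficient (one row per gene)."""
    df = pd.read_csv(path, sep="\t", dtype={"model_name": str, "gene_id": str})
    required = {"model_name", "gene_id", "coefficient"}
    if not required.issubset(df.columns):
        raise ValueError(f"model file must have columns {sorted(required)}")
    models: dict[str, SignatureModel] = {}
    for name, grp in df.groupby("model_name", sort=False):
        models[str(name)] = SignatureModel(
            gene_ids=tuple(grp["gene_id"]),
            coefficients=tuple(float(c) for c in grp["coefficient"]),
        )
    return models


def write_models_tsv(models: Mapping[str, SignatureModel], path) -> None:
    rows = [
        {"model_name": name, "gene_id": g, "coefficient": c}
        for name, model in models.items()
        for g, c in zip(model.gene_ids, model.coefficients)
    ]
    pd.DataFrame(rows, columns=["model_name", "gene_id", "coefficient"]).to_csv(
        path, sep="\t", index=False
    )
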