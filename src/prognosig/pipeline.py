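"""End-to-end orchestration: load or simulate, filter, split, screen,
search, evaluate, and optionally compare — with seed-reproducible reports.

All randomness flows from a single root seed, expanded deterministically per
stage, so partial reruns and full reruns with the same config are
byte-identical.  Reports are plain JSON/TSV.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import cohort_io, comparison, evaluation, search, synthetic
from .cohort_io import SurvivalCohort, ValidationError

__all__ = ["PipelineConfig", "run_full_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Configuration of a full run; defaults are the published pipeline's.

    Provide either ``expression_path``+``clinical_path`` or ``synthetic``.
    """

    output_dir: str = "prognosig_run"
    expression_path: str | None = None
    clinical_path: str | None = None
    already_log: bool = False
    synthetic: synthetic.SyntheticConfig | None = None
    external_expression_path: str | None = None  # cross-platform cohort (pre-logged)
    comparison_models_path: str | None = None
    train_fraction: float = 0.5
    screen_p_threshold: float = 0.001
    max_signature_size: int = 3
    workers: int = 1
    resample_repetitions: int = 1000
    resample_fraction: float = 0.5
    pcc_threshold: float = 0.6
    pcc_p_threshold: float = 0.01
    min_subgroup_n: int = 10
    subgroup_factors: tuple[str, ...] = ()
    run_coexpression: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None and not (self.expression_path and self.clinical_path):
            raise ValidationError(
                "config needs expression_path+clinical_path or a synthetic block"
            )
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must be in (0, 1)")
        for name in ("screen_p_threshold", "pcc_p_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1]")
        if not (0.0 < self.resample_fraction < 1.0):
            raise ValidationError("resample_fraction must be in (0, 1)")
        if self.max_signature_size < 1:
            raise ValidationError("max_signature_size must be >= 1")
        if self.workers < 1:
            raise ValidationError("workers must be >= 1")
        if self.resample_repetitions < 2:
            raise ValidationError("resample_repetitions must be >= 2")
        if not (-1.0 <= self.pcc_threshold <= 1.0):
            raise ValidationError("pcc_threshold must be in [-1, 1]")
        for f in self.subgroup_factors:
            if f not in ("gender", "stage", "grade"):
                raise ValidationError(f"unknown subgroup factor {f!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "planted_genes" in syn:
                syn["planted_genes"] = tuple(syn["planted_genes"])
            if "planted_betas" in syn:
                syn["planted_betas"] = tuple(syn["planted_betas"])
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        if "subgroup_factors" in raw or isinstance(cfg.subgroup_factors, list):
            cfg.subgroup_factors = tuple(cfg.subgroup_factors)
        return cfg


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_cohort(config: PipelineConfig, log: list[str]) -> SurvivalCohort:
    if config.synthetic is not None:
        cohort = synthetic.generate_cohort(config.synthetic)
        log.append(
            f"simulate: n_samples={cohort.n_samples} n_genes={len(cohort.gene_ids)} "
            f"seed={config.synthetic.seed}"
        )
        return cohort
    expr = cohort_io.read_expression(config.expression_path, already_log=config.already_log)
    clin = cohort_io.read_clinical(config.clinical_path)
    log.append(f"load: clinical rows dropped={clin.n_dropped}")
    cohort = cohort_io.assemble_cohort(expr, clin.records)
    log.append(f"load: cohort n_samples={cohort.n_samples} n_genes={len(cohort.gene_ids)}")
    return cohort


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write reports under ``config.output_dir``.

    Returns a summary dict (also written as summary.json).  Identical
    config + seed produce byte-identical reports.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed: root={config.seed}"]

    cohort = _load_cohort(config, log)
    filtered, n_kept = cohort_io.filter_low_expression(cohort)
    log.append(f"filter: retained {n_kept} of {len(cohort.gene_ids)} genes")

    train, validation = cohort_io.split_cohort(
        filtered, config.train_fraction, stage_seed(config.seed, "split")
    )
    log.append(f"split: train={train.n_samples} validation={validation.n_samples}")

    screen = search.univariate_screen(train, config.screen_p_threshold)
    log.append(f"screen: {len(screen.candidate_gene_ids)} candidates "
               f"at P<{config.screen_p_threshold}")
    _write_json(screen.to_dict(), out / "screen.json")

    result = search.exhaustive_search(
        train, screen, max_size=config.max_signature_size, workers=config.workers
    )
    log.append(
        f"search: enumerated={result.n_enumerated} "
        f"skipped={result.n_skipped_nonconverged} "
        f"best={list(result.best.gene_ids)} auc={result.best.training_auc:.4f}"
    )
    _write_json(result.to_dict(), out / "search.json")

    model = result.best
    reports = {}
    for name, part in (("train", train), ("validation", validation)):
        rep = evaluation.evaluate_model(model, part)
        reports[name] = rep
        _write_json(rep.to_dict(), out / f"evaluation_{name}.json")
        log.append(
            f"evaluate[{name}]: auc={rep.auc.auc:.4f} c={rep.concordance.c_index:.4f} "
            f"logrank_p={rep.logrank.p_value:.3g}"
        )

    summary: dict = {
        "config_seed": config.seed,
        "n_samples": cohort.n_samples,
        "n_genes_input": len(cohort.gene_ids),
        "n_genes_filtered": n_kept,
        "n_candidates": len(screen.candidate_gene_ids),
        "n_enumerated": result.n_enumerated,
        "best_model": model.to_dict(),
        "train": {
            "auc": reports["train"].auc.auc,
            "c_index": reports["train"].concordance.c_index,
            "logrank_p": reports["train"].logrank.p_value,
            "mean_survival_low": reports["train"].mean_survival_low,
            "mean_survival_high": reports["train"].mean_survival_high,
        },
        "validation": {
            "auc": reports["validation"].auc.auc,
            "c_index": reports["validation"].concordance.c_index,
            "logrank_p": reports["validation"].logrank.p_value,
            "mean_survival_low": reports["validation"].mean_survival_low,
            "mean_survival_high": reports["validation"].mean_survival_high,
        },
    }

    if config.external_expression_path:
        ext = cohort_io.read_expression(config.external_expression_path, already_log=True)
        clin_ids = [s for s in ext.sample_ids if s in set(cohort.sample_ids)]
        ext_cohort = SurvivalCohort(
            expression=cohort_io.ExpressionMatrix(ext.data[clin_ids]),
            clinical=cohort.clinical.loc[clin_ids],
        )
        rep = evaluation.evaluate_model(model, ext_cohort)
        _write_json(rep.to_dict(), out / "evaluation_external.json")
        summary["external"] = {
            "auc": rep.auc.auc,
            "c_index": rep.concordance.c_index,
            "genes_missing": rep.genes_missing,
        }
        log.append(f"evaluate[external]: auc={rep.auc.auc:.4f} "
                   f"missing={rep.genes_missing}")

    for factor in config.subgroup_factors:
        sub = evaluation.subgroup_evaluate(
            model, filtered, factor, min_n=config.min_subgroup_n
        )
        _write_json(
            {
                lv: (None if rep is None else rep.to_dict())
                for lv, rep in sub.items()
            },
            out / f"subgroups_{factor}.json",
        )
        log.append(f"subgroups[{factor}]: levels={sorted(sub)}")

    if config.run_coexpression:
        hits = evaluation.coexpression_screen(
            filtered,
            list(model.gene_ids),
            pcc_threshold=config.pcc_threshold,
            p_threshold=config.pcc_p_threshold,
        )
        _write_json({"hits": [h.to_dict() for h in hits]}, out / "coexpression.json")
        summary["n_coexpression_hits"] = len(hits)
        log.append(f"coexpression: {len(hits)} hits")

    if config.comparison_models_path:
        others = comparison.read_models_tsv(config.comparison_models_path)
        all_models = {"searched_signature": model, **others}
        rep = comparison.resample_compare(
            filtered,
            all_models,
            repetitions=config.resample_repetitions,
            fraction=config.resample_fraction,
            seed=stage_seed(config.seed, "compare"),
        )
        _write_json(rep.to_dict(), out / "comparison.json")
        per_resample = rep.auc_samples.add_prefix("auc_").join(
            rep.c_samples.add_prefix("c_")
        )
        per_resample.to_csv(out / "comparison_resamples.tsv", sep="\t", index_label="resample")
        summary["comparison_mean_auc"] = rep.mean_auc
        log.append(f"compare: {len(all_models)} models, R={config.resample_repetitions}")

    _write_json(summary, out / "summary.json")
    (out / "run.log").write_text("\n".join(log) + "\n")
    for line in log:
        logger.info(line)
    return summary
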