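# prognosig

Discovery and evaluation of small prognostic gene-expression signatures
for survival cohorts (e.g. RNA-seq tumor cohorts with follow-up data).

Given a genes × samples expression matrix (log2(x+1)-normalized) and a
clinical table (survival time in days, vital status, gender/stage/grade/
age), the pipeline:

1. drops genes that are zero in more than half the samples,
2. splits the cohort into training and validation halves,
3. screens every gene with a univariate Cox proportional-hazards Wald test
   (P < 0.001),
4. **exhaustively traverses all 1–3-gene combinations** of the surviving
   candidates, fits each by multivariate Cox on the training half, and
   keeps the combination whose risk score maximizes the training ROC-AUC,
5. evaluates the winning signature on the validation half (and optionally
   on a cross-platform cohort that lacks some signature genes): median
   risk-score split, Kaplan–Meier curves, log-rank test, ROC-AUC and
   Harrell's C-index with 95% CIs,
6. optionally compares the signature against published models by repeated
   random 50% subsampling with Welch t-tests on the per-resample AUCs.

The risk score of a signature with genes g and Cox coefficients β is

```
score_i = Σ_g β_g · E_{g,i}
```

with E the log2-scale expression, larger scores meaning higher hazard.
Cox fitting (Efron ties, Newton–Raphson), Kaplan–Meier, log-rank,
Harrell's C and the Mann–Whitney/DeLong AUC are implemented from first
principles in `prognosig.survival`; a synthetic-cohort generator
(`prognosig.synthetic`) plants signatures under a proportional-hazards
model so the whole pipeline is testable end-to-end without external data.
See `docs/methods.md` for the model and the design choices.

## Worked example

Run the full pipeline on a simulated 300-sample cohort with a planted
3-gene signature (coefficients 0.9, −0.8, 0.7 on genes G00000–G00002):

```python
from prognosig import PipelineConfig, SyntheticConfig, run_full_pipeline

config = PipelineConfig(
    output_dir="demo_run",
    synthetic=SyntheticConfig(
        n_samples=300, n_genes=50, planted_genes=(0, 1, 2),
        planted_betas=(0.9, -0.8, 0.7), censor_rate=0.4,
        expression_scale=1.0, zero_inflation=0.1, seed=5,
    ),
    seed=5,
)
summary = run_full_pipeline(config)
```

The summary (also written to `demo_run/summary.json`) contains:

```
n_candidates: 3          # genes surviving the P < 0.001 screen
n_enumerated: 7          # all 1-3 gene combinations traversed
best_model:
  gene_ids:     ["G00000", "G00001", "G00002"]
  coefficients: [0.774, -0.952, 0.670]
  training_auc: 0.812
train:       auc 0.812, C-index 0.814, log-rank P 9.5e-12,
             mean survival low/high risk 841 / 268 days
validation:  auc 0.836, C-index 0.865, log-rank P 4.4e-20,
             mean survival low/high risk 866 / 211 days
```

The search recovered exactly the planted trio with coefficients close to
the planted (0.9, −0.8, 0.7); the AUC ≈ 0.81 and C-index ≈ 0.81 on held-out
samples show the score separates fast from slow progressors, and the
median split yields a low-risk group living ~3–4× longer on average.

The same stages are available from the shell (`prognosig simulate`,
`screen`, `search` — with `--chunk i/w` and `merge-search` for resumable
large traversals — `evaluate`, `compare`, `run`); every report is plain
JSON/TSV and byte-identical for a fixed config and seed.

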