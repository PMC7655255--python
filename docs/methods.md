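# Methods

`prognosig` implements a survival-signature discovery pipeline for
expression cohorts: prevalence filtering, univariate Cox screening,
exhaustive best-subset search of small multivariate Cox models under a
training-ROC-AUC objective, risk-score stratification with Kaplan-Meier /
log-rank / C-index / AUC evaluation, cross-platform projection, Pearson
coexpression screening, and a resampling harness for comparing competing
signatures.  This note records the model, the choices that were genuinely
open, and what the synthetic validation does and does not establish.

## Statistical model

**Cox proportional hazards.**  For expression vector `x_i` the hazard is
`h_i(t) = h_0(t) exp(beta' x_i)`.  Coefficients maximize the log partial
likelihood with the **Efron correction** for tied event times
(day-resolution survival data tie frequently; Efron is the accepted default
and less biased than Breslow under heavy ties; on tie-free data the two
coincide, which the tests exercise).  Optimization is Newton-Raphson with
step-halving.  Convergence requires either a parameter step below `tol`
(default 1e-9) or a score below `tol` *together with* a small step — a
vanishing score alone is not trusted, because under monotone likelihood
(perfect separation) the score decays exponentially while the estimate
still advances by O(1) per iteration.  Fits are flagged non-convergent when
any |coefficient| exceeds 20 on the log-hazard-ratio scale, and
additionally when the reported standard error degenerates (zero or > 1e3
with a nonzero coefficient), which happens when a flat likelihood lets the
score underflow before the coefficient bound trips.  Non-convergent fits
are skipped by the search rather than scored, so separation can neither win
nor poison the argmax.

**Wald tests** use z = coefficient / SE with two-sided normal tails; the
SE comes from the inverse observed information.

**Kaplan-Meier / log-rank.**  Standard product-limit estimator; two-group
log-rank with hypergeometric expectations and variance, chi-square with
1 df.  Zero total variance returns P = 1 with a warning.

**Harrell's C.**  Pair (i, j) is comparable iff `t_i < t_j` and subject i
died; tied risk scores earn half credit; pairs tied on time with two deaths
are not comparable.  The SE is the Noether-type approximation
`sqrt(c(1-c)/pairs)` with a normal 95% CI truncated to [0, 1]; exact
pair-resampling variances are deliberately out of scope (any consistent
estimator yields interchangeable CIs at cohort sizes of interest).

**ROC-AUC.**  The label is end-of-follow-up vital status (death = 1), the
predictor is the risk score; the estimate is the Mann-Whitney probability
with ties at half credit, and the variance is DeLong's placement estimator.
A time-dependent ROC is intentionally not implemented: the pipeline
reports one AUC per cohort.

## The discovery procedure

1. **Prevalence filter**: keep genes nonzero in at least `ceil(n/2)`
   samples ("at least half" is ambiguous at odd n; the ceiling rule is the
   stricter reading and the fraction is configurable).
2. **Split**: unstratified simple random train/validation split (default
   50/50, sizes `round(n f)` / remainder), seed-reproducible.
3. **Screen**: one univariate Cox fit per gene; keep converged fits with
   Wald P < 0.001 (default), in stable input order.
4. **Search**: traverse *every* combination of 1..3 candidates (sizes
   ascending, lexicographic within size).  Each combination is fit by
   multivariate Cox **on the training cohort** and scored by the AUC of its
   training risk scores — the validation cohort is never touched by the
   search.  The argmax tie-break is (higher AUC, fewer genes,
   lexicographically smallest gene set), which makes serial, multi-worker
   and chunked traversals bit-identical; contiguous index ranges support
   resumable full-scale runs (415 candidates = 11,912,575 combinations).
5. **Risk score**: `score_i = sum_g beta_g E_{g,i}` with the multivariate
   coefficients; cohorts are dichotomized at the median score (sorted by
   (score, sample ID); odd n puts the extra sample in the low-risk group;
   boundary ties resolve by sample ID).
6. **Cross-platform projection**: when another platform lacks signature
   genes, available terms keep their original coefficients and missing
   terms contribute zero; the model is reused, not refit (refitting is
   available as an explicit separate step: just fit the available genes).
   Mean survival per risk group is the arithmetic mean of observed
   follow-up times; the KM restricted mean is a noted alternative but not
   the default.
7. **Coexpression screen**: Pearson r of every non-marker gene against
   each signature gene, t-distribution P; retained when r > 0.6 (signed,
   as a positive-coexpression screen; an absolute-value mode exists) and
   P < 0.01.
8. **Model comparison**: R = 1000 random 50% subsamples drawn without
   replacement (redrawn, with a bounded retry budget, if a draw lacks an
   outcome class), each model scored on each subsample via projection;
   pairwise two-sided Welch t-tests on the AUC vectors.  Subsamples are
   shared across models (paired design — lower variance; an unpaired mode
   exists).  Identical AUC vectors report P = 1 by convention and are
   flagged.

## Synthetic cohorts

`SyntheticConfig` defaults define the package's reference study
conditions: 370 samples, 500 genes, ~65% censoring, day-resolution times,
log2-scale expression `max(0, N(3.0, 1.5^2))` with 20% zero-inflation, and
a 3-gene planted signature whose coefficients are the published
hepatocellular-carcinoma model's (0.7675, 0.1726, -0.2466).  Event times
are exponential with hazard `h0 exp(eta_i - mean(eta))`, `h0 = 1/800` per
day; centring the linear predictor is absorbed into the baseline hazard
(Cox inference is invariant) and keeps `h0` the hazard of a typical
sample.  Censoring is exponential with its rate chosen by a 1-d root solve
of `mean_i[c/(c + h_i)] = censor_rate` over the realized hazards — exact in
expectation even under planted signal, where the naive null-hazard formula
drifts.

The generator emulates exactly the structure the pipeline assumes —
independent genes, proportional hazards, independent censoring — and
none of the structure real cohorts add: gene-gene correlation, batch
effects, platform-specific distributions, informative censoring,
covariate-linked hazards.  Passing tests therefore certify the
*machinery* (estimators calibrated, search exact, projections faithful),
not that any particular real-data signature is reproducible.

## Numerical choices

- Linear predictors are centred before exponentiation inside the partial
  likelihood (the shift cancels exactly — one log-denominator per death),
  and clipped at ±500 to avoid overflow during wild Newton proposals.
- A constant covariate yields beta = 0, SE 0, P = 1 (no information), and
  counts as converged.
- Fitting is guarded against overfit: at most max(1, n/5) covariates.
- The search's fast AUC and the reported `roc_auc` use the same rank-based
  Mann-Whitney formula, so search bookkeeping and final reports agree
  bitwise.
- All pipeline randomness derives from one root seed expanded per stage
  (CRC-keyed SeedSequence), so partial reruns reproduce full runs.

## Problem sizes used in the test suite and acceptance script

Chosen to exercise each property at the smallest scale where it is
statistically decidable: oracle equivalence on 100 cohorts of n <= 10;
log-rank type-I error on 5000 null simulations (2 x 100); coefficient
recovery at n = 2000 over 20 seeds; planted-trio recovery with 3 signal +
20 noise genes at n = 400 over 20 seeds; screening calibration with 1000
null genes; the headline pipeline on the 370-sample reference cohort.

## Known limitations

- No stratified, time-varying, or penalized Cox variants; no multi-group
  log-rank; no competing risks.
- The exhaustive search is exponential in signature size by design; sizes
  above ~3 on hundreds of candidates require the chunked/parallel path.
- The AUC and C-index confidence intervals are large-sample
  approximations; at very small n or few events they can be optimistic.
- Cross-platform evaluation applies log-scale coefficients to the other
  platform's log-scale values as-is; systematic platform shifts degrade
  transfer and are not corrected (no cross-platform normalization).
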