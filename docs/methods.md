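# Methods

This note documents the statistical procedures implemented in `metabosurv`,
the modeling assumptions behind them, the defaults and why they were
chosen, and what the synthetic benchmark does and does not establish.

## Synthetic cohort model

The generator (`metabosurv.synthetic`) emulates a targeted-metabolomics
survival study of a CAD cohort. Its default configuration describes the
conditions the pipeline is designed for: 1040 study samples, 202
metabolites, 4 analytical batches with a pooled-QC injection every 10 study
injections, and censored endpoints with roughly 60–80 deaths and 170–210
MACEs over a median follow-up of about 3–3.5 years.

**Intensities.** Each metabolite has a lognormal baseline (1e3–1e6 counts).
An injection's intensity is baseline × batch factor (lognormal, σ = 0.15)
× (1 + drift), where drift ramps linearly from 0 to `drift_amplitude`
(default 0.3) across each batch, × biological variation
(lognormal, CV 0.35, study samples only) × analytical noise (lognormal, CV
0.10, all injections). QC injections draw from the pooled profile, so they
carry batch, drift and analytical noise but no biological term. The lowest
`lod_quantile` (default 3%) of each metabolite's values are recorded as
missing — left-censoring only, matching the minimum-substitution imputation
rule; there is no MCAR missingness by default.

**Outcomes.** A standard-normal latent matrix Z (SD units) drives the
biology. LVEF = 60 + Σ mediator_effects·Z + N(0, 5²) percent; LVMI is
anti-correlated with LVEF plus noise. The log-hazard is
Σ hazard_effects·Z + mediator_hazard·(LVEF − 60) + 0.35·(standardized age)
+ 0.35·diabetes. Event times are Weibull proportional-hazards draws (shape
1.2; death scale 75 y, non-fatal scale 30 y — calibrated so default event
counts land near the conditions above); MACE time = min(death, non-fatal),
which enforces death ⊂ MACE by construction. Censoring is
Uniform(0.1, `followup_max` = 7) years — staggered entry with an
administrative cutoff, giving a median follow-up near 3.5 y — plus an
exponential loss-to-follow-up at 0.02/y. The censoring distribution and
baseline hazard are conventions of this package, not field constants; both
are configurable.

**Confounders.** The 17 clinical covariates used in adjusted analyses
(age, sex, AST, eGFR, diabetes, hypertension, SBP, glucose, cholesterol,
HDL-C, PPI, ACEI, β-blocker, CCB, current smoking, family history of CVD,
SYNTAX) are generated as mixed continuous/binary variables. Standardized
age and diabetes additionally load (strength 0.2) onto every third
metabolite and enter the hazard, so confounder adjustment is non-trivial.

**Genotypes.** Additive 0/1/2 dosages in Hardy–Weinberg proportions at
MAFs drawn from `maf_range`; optional LD blocks by copy-with-mutation
(block members co-located within 10 kb in the position map). Instrument
SNPs shift their target latent metabolite by effect × allele count in SD
units. A SNP→metabolite summary-statistics table (beta, SE, P from simple
regression on the latent levels) is emitted in the layout of an external
metabolome-GWAS, which is how real instrument sources arrive.

The generating truth (signature set, causal effects, closed-form mediation
proportions) is serialized to `truth.json` next to the data.

**What the benchmark does not emulate:** chromatography/spectra, non-left-
censored missingness, non-proportional hazards, population stratification
or realistic LD beyond single blocks, measurement-batch interactions with
biology. Passing tests therefore demonstrate correctness of the statistics
under the stated model, not robustness to every pathology of real data.

## Preprocessing

Order is fixed and enforced: CV filter → LOD imputation → QC-RLSC → Pareto
scaling.

- CV uses raw intensities (sd/mean, ddof = 1) over QC injections; the
  removal rule is strictly CV > 0.5, so a feature at exactly 50% is kept.
- QC-RLSC fits, per block and feature, a robust LOESS (local quadratic,
  tricube weights, span 0.75, two bisquare re-weighting passes) of QC
  intensity on injection order, evaluates it at every injection, divides,
  and multiplies by the feature's QC median across all blocks — the global
  multiplier is what removes between-block offsets. Evaluation outside the
  first/last QC uses the boundary fit. Blocks with < 5 QC points for a
  feature fall back to a constant block-median correction with a warning.
  A non-positive drift fit raises, naming the feature and sample; negative
  corrected values are floored at the feature's minimum observed value.
  The LOESS is written in-package because the spec of the correction is a
  degree-2 robust local fit and the installed smoothers are degree-1 only.
  Span and degree are documented defaults, not literature constants.
- Pareto scaling is per analytical block: x' = (x − mean)/√sd, constant
  features centered only. QC rows are dropped from the modeling matrix at
  this point. Pareto leaves column variance equal to the original SD, so
  the screening layer re-standardizes to unit SD to report per-SD effects.

## Screening

One fit per metabolite: Cox PH (Efron ties, two-tailed Wald tests) for
death/MACE, OLS for LVEF/LVMI, optionally adjusted for the 17 confounders
(the same set is the default for the linear screens; it is configurable).
BH-FDR is applied across metabolites within each (model, endpoint) family;
non-converged fits are flagged and excluded from the family size. The
discovery rule is adjusted FDR < 0.05; replication in an independent
cohort uses P < 0.05.

Unadjusted screens on a complete matrix use a vectorized one-dimensional
Newton solver (Efron ties) across all metabolites simultaneously; it is
pinned against lifelines in the tests to rel. 1e-5 and exists because
calibration studies fit tens of thousands of univariate models. Adjusted
screens go through lifelines.

## Signature selection

Per repeat, folds are reshuffled (stratified by event status so no fold is
event-free), the L1 path is fit with confounders at penalty factor 0
(scikit-survival Coxnet), the penalty is chosen by mean held-out deviance
(−2 × Breslow partial log-likelihood on the left-out fold; Breslow because
held-out ties are rare and the criterion is evaluated thousands of times),
and the model is refit on the full data at that penalty. Defaults: 10
folds, 200 repeats, deviance-minimizing λ (a 1-SE rule is available by
flag — the sources describing this design do not state min vs 1-SE).
Reported coefficients average over **all** repeats including zeros, which
is what produces the characteristic small-β-at-low-frequency pattern of
published frequency tables; averaging over nonzero repeats only is
available. Candidates with frequency 0 are removed before model building.

## Prognostic models and evaluation

- Stepwise search is bidirectional on the partial-likelihood AIC from the
  empty model, with candidates sorted by name so the path is deterministic,
  followed by iterative removal of variables with Wald P ≥ 0.1. The four
  model families (clinical, reference-biomarker+clinical, metabolomic,
  metabolomic+clinical) are a configuration-level enumeration over the same
  builder.
- h(X) = exp(Σβ_i x_i); absolute risk at horizon t is 1 − S(t|X) from the
  fitted model's Breslow baseline.
- The evaluation horizon defaults to the cohort's median follow-up and is
  overridable; time-dependent AUC is the IPCW cumulative/dynamic estimator
  (scikit-survival), reported in percent, with 50 returned for a
  zero-variance score.
- IDI and continuous NRI are computed from the two risk vectors with event
  status assessed at t; samples censored before t are excluded (a standard
  simplification — IPCW reclassification weights are out of scope).
  Bootstrap CIs (default 1000 replicates) resample the per-sample
  (risk_new, risk_ref, status) triples without refitting the Cox models;
  refitting inside the bootstrap would require the models, not the scores,
  and is intentionally outside this function's contract.
- Youden cutoffs enumerate all observed score values; ties in J resolve to
  the smallest cutoff.
- Stratification uses score quartiles (low < Q1, middle Q1–Q3 inclusive,
  high > Q3) and the 3-group log-rank test. In validation, quartiles are
  computed within the validation cohort's own scores by default (a flag
  allows discovery-derived cutoffs); discovery coefficients are applied
  frozen, and a missing model variable aborts with its name.

## Correlation network

All pairwise Spearman correlations among outcome-associated metabolites
and clinical factors; an edge requires P < 0.01 and |ρ| > 0.1 if either
node is clinical, |ρ| > 0.2 for metabolite–metabolite pairs. Mixed pairs
default to the looser clinical threshold (configurable — the convention is
genuinely ambiguous). P-values use the tie-corrected t approximation, or
an exact pairing-permutation test for n < 20. Output is an edge list and
GraphML; layout/rendering is left to graph viewers.

## Mendelian randomisation

One-sample 2SLS. Instruments: SNPs with summary P < 1e-5 per metabolite,
then greedy LD pruning by ascending P keeping a SNP iff r² < 0.001 with
every kept SNP within 10,000 kb (dosage Pearson r², missing genotypes
mean-imputed for LD only; SNPs beyond the window or on other chromosomes
are treated as independent). Stage 1 regresses the exposure on all
retained instruments jointly (collinear instruments dropped with a
warning; F < 10 warns of weak instruments). Stage 2 regresses the outcome
on the fitted exposure — Cox with Efron ties for death/MACE (HR, 95% CI),
OLS for LVEF/LVMI (estimate ± SE). Second-stage SEs condition on the first
stage (the generated-regressor issue, unavoidable in the survival case); a
bootstrap option re-runs both stages on resampled rows. Covariates may
enter stage 2; the death/MACE stage is unadjusted by default. Genotype
principal components for structure adjustment are available via
`genotype_pcs`.

## Mediation

The four-step product-of-coefficients decomposition with X = metabolite
(SD units), M = LVEF, Y = event by end of follow-up (dichotomous;
follow-up time is deliberately discarded here — this reproduces the
classical four-model procedure, it is not a recommendation). Y-models use
a probit (latent-scale) link by default, consistent with the
categorical-endogenous convention of structural-equation software; a
linear option exists and makes the additivity identity c = c′ + β₁β₂ exact,
which the tests exploit. The proportion mediated (β₁β₂)/c is computed on
the fitted link's scale, reported only when |c| exceeds a tolerance
(division guard), and flagged for reporting only when both the total and
the mediated effect are significant at 0.05 (dual-significance rule).
Inference is percentile bootstrap (default 1000 replicates; the mediated-
effect P is the two-sided bootstrap tail probability with a 2/(B+1)
resolution floor).

## Orchestration and reproducibility

`run_discovery` executes preprocess → screen → select → model → network →
MR → mediation, writing TSV/JSON stage outputs and a manifest with input
SHA-256 hashes and per-stage seeds derived from the master seed via
`SeedSequence(master, spawn_key=(stage_index,))`, so each stage is
independently reproducible and a rerun is byte-identical (the test suite
asserts this at the hash level). Stages communicate only through
serialized files. All thresholds live in `PipelineConfig` with the
standard defaults (CV 0.5, FDR 0.05, 10×200 LASSO, retention P 0.1,
ρ 0.1/0.2 at P < 0.01, MR P 1e-5, LD r² 0.001 / 10,000 kb, 1000
bootstrap) and are overridable from YAML.

## Problem sizes used in the checks

The test suite runs calibration studies at n = 1000 (screening; 200 cohort
draws for the null, 60 for power), n = 800 with 20 repeats (stability
LASSO, scaled from the 200-repeat default), n = 500 × 50 draws
(stratification power), n = 5000 (2SLS recovery) and n = 10000 (mediation
closed form). `scripts/acceptance.py` runs the full pipeline at the
default cohort scale (1040 × 202 discovery, 566 validation) with 100 LASSO
repeats and 500 bootstrap replicates — representative fractions of the
full-size defaults chosen as the package's standard demonstration sizes.

## Known limitations

- No competing risks, time-varying covariates, calibration metrics or
  penalized final models.
- IDI/NRI exclude censored-before-horizon samples rather than weighting.
- One-sample 2SLS only: no IVW/MR-Egger/weighted-median estimators or
  pleiotropy sensitivity analyses.
- Mediation is the classical product-of-coefficients procedure, not a
  counterfactual natural-effects estimator, and ignores survival time.
- The LOESS span/degree of QC-RLSC are package defaults; sources describing
  the algorithm do not fix them.
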