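# Methods

This note documents the models, numerical choices and limitations of
`dietmicro`, and what the synthetic cohort does and does not emulate.

## Dietary scoring

An index is a list of (food subgroup, weight) pairs; the raw score is the
weighted sum of servings/day and is linear in intake. Item frequencies are
averaged across repeat FFQ records *before* serving-size standardization;
both operations are linear so the order is immaterial, and it is fixed for
determinism.

Energy adjustment uses the residual method: the raw score is regressed on
total energy intake (simple linear model with intercept) and replaced by the
residual plus the cohort mean raw score. Adding the mean back keeps scores
on an interpretable scale; it shifts every score equally, so quintiles,
standardized scores and regression slopes are unchanged by that choice.
Constant energy is an error — the residual is undefined. Quintiles are
assigned on the energy-adjusted score (rank-based, lowest fifth = Q1, larger
groups at the low end when n is not divisible by 5, ties broken by stable
participant-id order so assignment is deterministic).

HOMA-IR = insulin (μIU/ml) × glucose (mmol/L) / 22.5 and is recomputed from
period-averaged insulin and glucose rather than averaged from per-visit
values; with repeated measurements of a ratio the two differ, and averaging
the analytes first matches how the mean is taken for the measured markers.

## Microbiome preparation

Boundary semantics are deliberate and tested: the depth filter drops samples
*strictly below* the threshold (default 10,000 reads; a sample at exactly
10,000 is retained), and the prevalence filter keeps genera with a nonzero
count in *strictly more than* the threshold fraction of samples (default
0.90). "Present" means a nonzero count, not a minimum abundance.

Alpha diversity (Shannon in nats, Pielou evenness) is computed on the full
genus composition of depth-passing samples, before prevalence filtering —
the filter exists for the regression design matrix, not for diversity, which
follows the usual vegan-style convention of using the whole composition. A
single-genus sample has H = 0 and undefined (missing) evenness.

The CLR transform adds the pseudocount to *counts* (cᵢ + 1), not to
proportions; the pseudocount choice is isolated in one function argument.
CLR rows sum to zero by construction (tested at 1e-9), and with increasing
depth the pseudocount CLR converges to the proportion-based CLR (tested by
comparing depth 10³ vs 10⁶ replicates of one composition).

## Profile signature

The dietary score is regressed on CLR genus abundances with an elastic net.
Predictors are standardized to unit variance inside the fit using
training-set statistics, which travel with the serialized profile;
coefficients are reported on the standardized scale. The penalty strength
and the L1/L2 mixing parameter are tuned jointly — mixing over
{0.1, 0.3, 0.5, 0.7, 0.9}, penalty over a 100-point automatic path — by
10-fold cross-validation. Fold assignment keeps co-twins in the same fold by
default (a leakage guard; plain random folds are available by switch).

The penalty is chosen by the one-standard-error rule: the strongest penalty
whose CV mean squared error is within one SE of the minimum, the familiar
glmnet default. The CV-minimum rule is available (`selection_rule="min"`)
but is deliberately not the default: minimum-MSE selection is liberal and
admits spurious genera when the score carries no microbiome signal at all
(measured ~6% of genera selected on pure noise at n = 700, versus 0% under
the 1-SE rule), while signal recovery under the 1-SE rule is undiminished
(10/10 planted genera, test-set Spearman ≈ 0.88 at the default effect size).
The 1-SE rule also yields selected-set sizes (≈ 15–35 genera) in the range
reported for signatures of this kind.

Profile scores are intercept-free weighted sums Σ β_g · z(CLR_g). Test-set
participants are scored by the model fit on the full training set; training
participants are scored leave-one-out — refit at the tuned hyperparameters
on the remaining n−1, with standardization constants recomputed each time —
so all downstream scores are out-of-sample. The biomarker models consume the
pooled (LOO + test) score column by default; the partition label is kept in
the output so either subset can be analysed alone.

## Association battery

All models are complete-case on the variables they use and report the
modelled n. The base covariate set: total energy intake, age, racial/ethnic
group, smoking status, supplement count, occupation, education, menopausal
status, hormone replacement therapy, fasted hours, NSAID use. Menopausal
status is a single 3-level factor (men / premenopausal / postmenopausal)
that also encodes sex; including a separate sex term would alias it. The
"+BMI" model adds BMI and changes nothing else. Twin-pair sensitivity models
add a random intercept per pair and zygosity as a fixed effect; a singular
mixed fit falls back to OLS with a logged warning and a zero variance
component.

Percent difference in a log outcome per SD of exposure is 100·(e^β − 1)
with the CI transformed endpoint-wise (the exact form for a log-linear
model, rather than the 100·β approximation). Quintile back-transformation
evaluates the adjusted linear predictor at the cohort means of continuous
covariates and reference levels of categorical ones; the relative value is
e^{β_q} with Q1 ≡ 1.

FDR control is Benjamini–Hochberg, applied within each exposure × model
family across its outcomes for the biomarker battery, and across tested
pathways for the screen; the family definition is recorded in the output.
The "probit transformation" of pathway abundances is the rank-based inverse
normal with the Blom constant, Φ⁻¹((r − 3/8)/(n + 1/4)) with average ranks
for ties — abundances are not probabilities, so a literal probit of the
values was rejected. Pathways with strictly more than 90% zeros are excluded
before transformation. The heatmap matrix z-scores each significant
pathway's quintile means across quintiles (sample SD), so each pathway row
has mean 0 and SD 1.

## Synthetic cohort

The generator emulates the *statistical shape* of a twin-registry diet–
microbiome study, not its marginal distributions: 131 FFQ items, 143
genera, compositional counts (log-normal latent abundances → multinomial at
a log-normal depth), biomarkers as exp(linear predictor + Gaussian noise),
zero-inflated pathways, and MZ/DZ within-pair correlation induced by shared
latent factors (never by copying rows, which would distort marginals). One
global seed drives independent per-stage substreams, so regenerating one
table leaves the others untouched.

Defaults, chosen once as the study conditions: 500 twin pairs (n = 1,000);
MZ fraction 0.5 with within-pair diet correlations 0.5 (MZ) / 0.25 (DZ); 10
signal genera per index at ±0.5 CLR-units per SD of the true score with
genus-level log noise SD 0.8; biomarker slopes 0.10 (log-insulin), 0.02
(log-glucose), 0.10 (log-CRP) per SD with total noise SDs 0.30/0.10/0.50 and
30% of noise variance shared within pairs; mean depth 30,000 reads
(log-normal, σ = 0.3) with 5% of samples planted below the 10,000-read QC
threshold; 200 pathways of which 20 carry a ~97% zero rate and 10 per
direction per index carry a ±0.4 log-scale effect. The true dietary score is
the planted weighted combination evaluated on the participant's record-mean
intakes — exactly the quantity the scoring pipeline recomputes — so score
recovery is testable to r > 0.99 and everything downstream has ground truth.

What passing tests therefore show: the pipeline's transforms, filters and
estimators recover known structure at realistic sample sizes and are
calibrated under the null. What they do not show: robustness to real-world
features the generator omits — taxon-specific overdispersion beyond the
multinomial, diet measurement error correlated with covariates, informative
missingness, batch effects, or real food/taxon label semantics.

## Known limitations

- The packaged serving map and EDIH/EDIP weights are synthetic structural
  stand-ins (the real component weights and NDSR assignments are not
  redistributable); analyses of real cohorts must supply their own files.
- Genus-level modelling only; no species/ASV-level signature.
- The pathway table is consumed as given (PICRUSt2-style output); no
  metagenome prediction is performed.
- Relative abundances throughout; absolute microbial load is not modelled.
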