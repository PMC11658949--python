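# dietmicro

Metabolic dietary pattern scores and their gut-microbiome profile signatures.

## The problem

Empirically derived dietary patterns — the Empirical Dietary Index for
Hyperinsulinaemia (EDIH) and the Empirical Dietary Inflammatory Pattern
(EDIP) — summarise how insulinaemic or pro-inflammatory a habitual diet is,
as a weighted sum of standardized food-group intakes. Both scores predict
metabolic disease risk, and one candidate mechanism is the gut microbiome:
diets that raise insulin or inflammation may do so partly by reshaping
microbial composition and function.

`dietmicro` implements the full analysis chain that connects these pieces in
a twin-cohort setting, for nutritional-epidemiology and microbiome
researchers who want a tested, reproducible reference implementation:

1. **FFQ harmonisation** — food-frequency items in servings/week, averaged
   over repeat records, mapped onto 170 standardized serving-size food
   subgroups (168 conventional subgroups plus pizza and cream soup treated as
   whole foods) in servings/day.
2. **Dietary index scoring** — raw score `S = Σᵢ wᵢ xᵢ` over subgroup
   servings `xᵢ`, energy-adjusted by the residual method (residual of `S` on
   total energy intake, plus the cohort mean), standardized, and cut into
   quintiles.
3. **Microbiome preparation** — sample depth QC (drop `< 10,000` reads),
   Shannon index `H = −Σ pᵢ ln pᵢ` and Pielou evenness `J = H / ln S`,
   prevalence filtering (keep genera present in `> 90%` of samples), and the
   centred log-ratio transform after a +1 pseudocount:
   `clrᵢ = ln(cᵢ+1) − (1/G) Σⱼ ln(cⱼ+1)`.
4. **Microbiome profile signature** — a 70/30 train/test split; elastic net
   regression of the dietary score on CLR genus abundances, tuned by 10-fold
   cross-validation (co-twins kept in the same fold); the profile score of a
   participant is the weighted sum of selected genera's standardized CLR
   values. Test participants are scored by the training-set model; training
   participants are scored leave-one-out to avoid over-fitting.
5. **Association battery** — covariate-adjusted linear models of circulating
   biomarkers (fasting insulin, glucose, HOMA-IR = insulin × glucose / 22.5,
   CRP) on the dietary and profile scores; percent difference in alpha
   diversity per SD (`100·(e^β − 1)`) and quintile back-transformation;
   twin-pair mixed models (random intercept per pair, zygosity adjusted);
   and a predicted-pathway screen (exclude `> 90%` zeros, Blom rank-probit
   transform, adjusted regression, Benjamini–Hochberg FDR at 0.1).

A synthetic twin-cohort generator (`dietmicro.synthetic`) produces every
input table with known planted structure — signal genera, biomarker slopes,
twin correlations, zero-inflated pathways — so each stage is testable
against ground truth. Cohort registry data are access-restricted; the
packaged serving map and index weights are synthetic structural stand-ins,
and real analyses must supply their own.

## Worked example

```bash
dietmicro --seed 5 --outdir run generate --pairs 50   # 100-participant cohort
dietmicro --seed 5 --outdir run all                   # full pipeline
```

which reports, stage by stage:

```
wrote cohort of 100 participants to run
intake.tsv: 100 participants
dietary_scores.tsv: 100 participants
93 samples pass QC
EDIH: 19 genera selected
EDIP: 17 genera selected
associations.tsv: 72 models
EDIH: 29 significant pathways
EDIP: 27 significant pathways
```

Seven of 100 samples were generated below the 10,000-read depth threshold and
dropped. The elastic net retained 19 genera for the EDIH signature (the ten
planted signal genera plus correlated neighbours). In `associations.tsv`, the
EDIH-related profile score is associated with higher fasting insulin —
β = 0.120 (95% CI 0.045–0.195) per SD on the log scale, n = 93 — and higher
HOMA-IR (β = 0.139, CI 0.056–0.223), mirroring the planted effects. In
`alpha_percent_diff.tsv`, Shannon diversity is 1.25% lower (CI −2.48 to
−0.01%) per SD of EDIH. The `pathway_screen_*.tsv` tables flag the planted
pathways at FDR < 0.1, and `pathway_heatmap_*.tsv` holds the quintile ×
pathway z-score matrices for plotting.

Every artefact carries the participant identifier, and re-running with the
same seed reproduces all outputs byte-identically (`manifest.json` records
the seed, thresholds and per-stage counts).

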