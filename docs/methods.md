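# Methods

`glyhome` implements the analytic pipeline of a nutritional-epidemiology
design relating dietary glycemic index (GI) and glycemic load (GL) to
glucose homeostasis and pre-diabetes in adults, including gene–diet
(GI × genetic risk score) and diet–diet (GI × cereal fiber) interactions.
Because studies of this kind rarely deposit participant-level data, the
package ships a synthetic-cohort generator calibrated so that the whole
pipeline — scoring, residual adjustment, tertiling, model fitting —
reproduces a realistic set of published effect sizes end to end. This note
documents the models, the calibration, and what the synthetic results do
and do not demonstrate.

## Dietary scoring

Each food's GI (glucose = 100 scale) is resolved by a fixed tier order:
a published value (`direct`), an explicit alias to a close match
(`close_match`), a carbohydrate-weighted mean over recipe ingredients
(`recipe`, Σ cho·GI / Σ cho, nested up to depth 5 with cycle detection), or
GI 0 for foods with < 5 g carbohydrate/100 g (`zero_rule`). The zero rule
dominates all other information. Close matching is an explicit alias
column rather than fuzzy string matching: GI matching in practice is a
manual judgement, and an alias column makes the assignment reproducible.
Recipe ingredient masses may total up to 105 g per 100 g of recipe to
absorb cooking water loss.

A day's glycemic load is GL = Σ cho_food · GI_food / 100 (grams of
glucose-equivalent carbohydrate); the dietary GI is 100·GL / total CHO.
Zero-rule foods therefore contribute carbohydrate but no load, diluting
the dietary GI, which is the intended behaviour for mainly-fat/protein
foods. Participant values are unweighted means over the available recall
days (1–3); no weekday/weekend weighting is applied. Cereal fiber is fiber
from foods flagged as cereals (rice, millet, noodles, bread, cookies,
crackers). Implausible energy intakes are excluded with inclusive bounds —
retained if 800 ≤ kcal/d ≤ 4200 (men) or 500 ≤ kcal/d ≤ 3500 (women) — the
literal reading of exclusion rules phrased as "<800 or >4200".

Exposures are energy-adjusted by the residual method, sex-specifically:
within each sex, OLS of the exposure on energy intake, keeping the
residual. Tertile cuts sit at the 33.33rd/66.67th percentiles of the
pooled residuals; ties go to the lower tertile (deterministic and
order-independent). A degenerate stratum with zero energy variance falls
back to mean-centering with a warning.

## Derived biomarkers

HOMA indices use the closed-form homeostasis-model equations,
IR = G·I/22.5 and β = 20·I/(G − 3.5) (glucose mmol/L, insulin μIU/mL).
The updated computer-model variant of these indices is an iterative
algorithm with no published closed form; the `homa2_approx` variant
multiplies the closed-form values by user-supplied recalibration constants
(defaults 1.0). All HOMA quantities in this package are therefore on the
closed-form scale, and HOMA-level contrasts are deliberately excluded from
the calibration targets: since FPG and insulin are generated and HOMA-IR
is always derived downstream as their product over 22.5, its contrast is
arithmetically the product of the FPG and insulin contrasts (≈22 %), which
cannot simultaneously match an independently reported HOMA2 contrast.

Pre-diabetes is FPG in [5.5, 7.0) mmol/L **or** HbA1c in [5.7, 6.4] %.
The FPG upper bound is exclusive (diabetes-range values are not
pre-diabetes); HbA1c bounds are inclusive; the 5.5 mmol/L lower cut is
implemented as printed in the definition adopted here (ADA-style criteria
use 5.6). Body-fat percentage is a pluggable linear form
a + b·BMI + c·WC + d·male; the default coefficients are a synthetic
surrogate (documented in `biomarkers.py`) chosen to land cohort medians in
the low twenties, since the canonical published coefficients are not
redistributable here; they can be replaced via the `coefficients` argument.

## Genetic risk score

The weighted GRS uses log-odds-ratio weights, w_i = ln(OR_i), normalised
as GRS = Σ w_i g_i / (2 Σ w_i) so the score lives on [0, 1] (0.5 = one
risk allele per SNP on average). This normalisation is invariant to
rescaling all log-weights and monotone in every dosage. The default panel
is 12 SNPs with odds ratios 1.10–1.45 and risk-allele frequencies whose
weighted mean is ≈0.80, putting the cohort mean score near 0.80. A
limitation worth noting: with 12 independent SNPs in Hardy–Weinberg
equilibrium this normalisation cannot produce a score SD much above 0.10,
so the generator's GRS SD (~0.08) is narrower than some published panels
report; the score's role as an interaction modifier only requires its
ranking, which is unaffected. Missing dosages are mean-imputed as
2·frequency; HWE is checked per SNP by a 1-df chi-square against expected
counts at the observed allele frequency, flagging p ≤ 0.01; call rate
< 99.5 % raises a QC flag without excluding the SNP.

## Association models

Continuous outcomes (FPG, HbA1c, insulin, HOMA-IR, HOMA-β) are
log-transformed and fitted by OLS on tertile indicators plus nested
covariate tiers:

| tier | covariates |
|---|---|
| 1 | age, sex |
| 2 | + smoking, physical activity, education |
| 3 | + cereal-fiber residual, protein residual |
| 4 | + body fatness |

plus the weighted GRS as a covariate by default (means are reported from
models "adjusting for GRS only", i.e. without interaction terms).
Group summaries are least-squares means — the model prediction with every
covariate at its sample mean (binary covariates at observed proportions) —
exponentiated back to the original scale with Wald 95 % intervals formed
on the log scale. With no covariates these reduce exactly to stratified
geometric means, which the tests assert to 1e-8. Trend tests replace the
tertile factor by the continuous residual. Pre-diabetes uses
maximum-likelihood logistic regression (Newton, BFGS fallback on stall),
tertile 1 as reference; trend again from the continuous-exposure logistic
model. No multiple-testing correction is applied anywhere; thresholds are
0.05 for main effects and 0.1 for interactions, recorded in the result
objects.

Interactions enter as a continuous exposure-residual × modifier product
(modifier = GRS or cereal-fiber residual) with a Wald test. Joint effects
are displayed as a 3 × 3 cross-classification with a single reference
cell; for the fiber cross-classification the continuous fiber residual is
dropped from the covariate list (`exclude_covariates`), because the cell
factor and the covariate are the same variable and keeping both would
adjust away the displayed contrast. The energy-partition model enters
energy from named food sources (here high-GI vs lower-GI staples) and the
remaining energy as separate continuous terms, so each coefficient is the
effect of adding energy from that source holding the rest fixed.

Rank-deficient designs raise an error naming the collinear columns rather
than silently dropping them; logistic separation raises an error
(penalized estimation is out of scope).

## Synthetic cohort and calibration

The generator (default n = 3918, 52.9 % female) emulates a rice-based
south-Chinese adult diet. A latent target GI per participant (truncated
normal, cohort mean ≈ 69, SD ≈ 7 after truncation) sets the share of
staple carbohydrate from a high-GI pool (sticky rice GI 83, steamed bread
GI 88, high-GI rice 72) versus a lower-GI pool (wheat noodles 46,
mung-bean noodles 39, black-rice porridge 42, lower-GI rice 55–62), with
zero-rule side dishes (vegetables, pork, egg, tofu, oil) and apple
(GI 28). Energy is log-normal around 1840/1520 kcal/d (men/women),
truncated to the plausibility bounds; a staple-share multiplier (SD 0.12)
decorrelates GL from GI (residual correlation ≈ 0.65); recall days get
per-food log-normal portion noise (SD 0.15) and participants have 3/2/1
recall days with probability 0.80/0.16/0.04. Catalog fiber contents were
chosen so the cereal-fiber residual is nearly uncorrelated with the GI
residual, letting the two be crossed cleanly in the 3 × 3 grids.

The outcome model is the critical design point: after the recalls are
generated, the generator scores them **through the same dietmetrics code
the pipeline uses** and computes the sex-specific energy residual of GI;
log-FPG, log-HbA1c and log-insulin are then drawn from linear predictors
in that residual, the standardized GRS, the standardized cereal-fiber
residual, the two product terms, and age/sex, plus Gaussian noise
(insulin noise correlated 0.4 with FPG noise). Because the observable
recalls and the latent exposure agree exactly, the pipeline's re-scored
exposure reproduces the generator's (tested to 1e-9), and fitted contrasts
are unattenuated. Pre-diabetes is never drawn: the pipeline classifies it
from the generated FPG/HbA1c, keeping the classification logic on the
test path.

Calibration solves, on the log scale, slope = log(target ratio) / Δr̄,
where Δr̄ is the extreme-tertile difference in mean GI residual measured
on a pilot draw, and anchors the intercept so the top-tertile
least-squares mean hits its target level; a self-consistency refinement
against the pilot tier-3 fit absorbs the small shift that covariate
adjustment induces. The defaults encode the refined solution for FPG
(top-tertile mean 5.67 mmol/L, extreme-tertile contrast ≈ 9 %), HbA1c
(top-tertile 5.82 %), and insulin (top-tertile 7.53 μIU/mL, contrast
≈ 12 %).

The pre-diabetes targets are shaped by the *window* structure of the
classification. Because both branches are intervals, an upward location
shift drains probability past the upper bound almost as fast as it adds
probability over the lower bound, so the odds ratio implied by a given
FPG contrast saturates. The generator exploits this deliberately: with a
residual log-SD of 0.30 for FPG and 0.20 for HbA1c, a 9 % adjusted FPG
contrast coexists with a top-tertile adjusted pre-diabetes odds ratio
near 1.1–1.2 and a top-tertile prevalence near 45–47 % — the qualitative
pattern of adjusted epidemiological estimates. These spreads are wider
than a tight laboratory panel would show; they are a calibration device,
and the narrow within-tertile interquartile ranges seen in real
descriptive tables are *not* reproduced. For the same reason the
generator's HbA1c contrast is small (~1 %): a double-digit HbA1c contrast
is arithmetically incompatible with the prevalence and odds-ratio targets
once the classification is derived rather than drawn. GRS and fiber
effects on the glucose branch (0.0455 and −0.054 per SD of log-FPG,
scaled down for HbA1c) place the (high GI, high GRS) cell elevation near
+24 % and the (high GI, low fiber) vs (low GI, high fiber) elevation near
+21 %, with GI × GRS and GI × fiber product coefficients sized so the
continuous interaction scan lands p < 0.1 in a typical draw.

One master seed spawns independent substreams (demographics, diet, recall
days, genotypes, outcomes, FFQ), so extending one component never
perturbs another; a fixed (config, seed) pair is bit-identical. The FFQ
view shrinks the diet preference toward the cohort mean (factor 0.7) and
adds item-level noise, giving a recall–FFQ GI correlation around 0.7 and
the expected regression-dilution attenuation in the FFQ sensitivity mode.

### What the synthetic results show — and what they do not

Passing the end-to-end suite shows that the scoring arithmetic, residual
adjustment, tertiling, model fitting and back-transformation chain is
correct and unbiased at realistic n, and that the generator's calibration
is self-consistent. It does **not** validate the substantive
epidemiology: the generator encodes the published effect structure by
construction, real recall data carry measurement error the generator
omits (no within-person systematic bias, no misreporting, no seasonal
structure), covariates are mutually independent where real ones are not,
and day-to-day variance uses a single configurable noise SD. Cell-level
cross-classification contrasts carry large Monte-Carlo noise even at
n = 3918 (a single cohort's (3,3)-cell odds ratio has a log-scale SD near
0.14), which is why the acceptance script averages replicate cohorts on
the log-odds scale.

## Problem sizes and numerics

Default analyses run at the design size n = 3918 (a full pipeline run is
about one second); unit and property tests use n = 400–1200 cohorts and
200–500-replicate Monte-Carlo loops, sizes chosen so the whole suite runs
in well under a minute while keeping binomial test bands tight enough to
detect real miscalibration. Tertile ties break to the lower group;
quantiles are linear-interpolation (`numpy` default); logistic fits try
Newton then BFGS; LS-mean intervals use 1.96·SE on the model scale.
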