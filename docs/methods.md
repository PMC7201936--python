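# Methods

## The question and the estimands

Two adiposity exposures are modelled per individual: a latent early-life
body size $L_E$ and a latent adult body size $L_A$, each observed as a
three-category measure (thinner / about average / plumper). The framework
estimates, for a disease outcome $Y$:

* the **total** effect of early-life body size (univariable IVW),
* the **direct** effects of early-life and adult body size (MVMR), and
* the **indirect** (adult-mediated) component, total − direct.

The two instrument sets are separable because some variants influence
body size predominantly in childhood, others predominantly in adulthood —
the property the stacked interaction analysis and the score/ROC validation
demonstrate on the synthetic data.

## Generative model

Genotypes are dosages $G \in \{0,1,2\}$ at biallelic variants with MAFs
uniform on a configurable range (default 0.05–0.45). LD is produced by a
liability-threshold model: within a block of size $b$, each haplotype's
allele indicators come from thresholding an equicorrelated multivariate
normal (correlation `ld_rho`), and two independent haplotypes are summed.
The implied population dosage correlation has a closed form through the
bivariate-normal orthant probability, which the tests use as the oracle.
With `ld_rho = 0` (the default) variants are independent Binomial(2, MAF)
draws.

Phenotypes follow a linear structural model with a shared Gaussian
confounder $U$ and unit-variance noise:

$$L_E = G b_E + c_E U + \epsilon_E, \qquad
  L_A = \theta L_E + G b_A + c_A U + \epsilon_A,$$

where $\theta$ (`beta_early_to_adult`, default 0.6) is the tracking of
body size into adulthood and $b_E, b_A$ are sparse per-allele effects
drawn N(0, 0.15) for 30 early-specific and 30 adult-specific variants out
of 100 (defaults; about 10–15 % of latent variance is genetic, a
realistic figure for large-effect adiposity loci). Small age, sex and
month-of-birth effects are placed on the latents so covariate adjustment
in the scans is exercised. Categories are assigned by cutting each latent
at the empirical quantiles of `category_proportions`; the adult trait is
cut at the **same** proportions as the early-life variable. The default
proportions are tertiles — the real survey proportions of the three
answers are not public, so the choice is exposed in configuration.

The outcome's linear predictor is
$\beta_{ED} X_E + \beta_{AD} X_A + c_Y U$ with $X$ either the latents
(default) or the categories (`outcome_scale="category"`); continuous
outcomes add unit noise, binary outcomes are Bernoulli(expit(α + η)) with
α solved for the requested prevalence. Age at menarche depends on $L_E$
only — by construction adult body size has no path to it, which is what
makes it a negative control. Under the latent-scale linear model the total
effect of $L_E$ is exactly $\beta_{ED} + \theta\,\beta_{AD}$ and the
indirect part is the product $\theta\,\beta_{AD}$.

### Misclassification of the reported early-life category

The early-life measure is a recalled category, so the generator supports a
reporting model: reported category $R$ drawn from a row-stochastic 3×3
confusion matrix given the true category. The bundled symmetric model
spills probability `rate` to adjacent categories, which keeps
$E[R \mid C]$ linear in $C$ with slope $1-\text{rate}$ — the reason purely
nondifferential error attenuates the early-life association uniformly. In
the *differential-on-adult* mode the row probabilities are exponentially
tilted by the individual's adult latent: reporting $r$ gets weight
$\exp(s\,L_A\,r)$, so with slope $s>0$ larger adults over-report their
childhood size at every true category. True categories are retained
alongside the reported ones for oracle comparisons.

## Scans and instrument selection

The association scan is per-variant least squares of the phenotype on
dosage with covariates, vectorised by Frisch–Waugh–Lovell residualisation;
a brute-force per-variant regression oracle pins it to 1e-10.
Coding the category 0/1/2 and fitting linearly asserts that moving from
the lowest to the middle category carries the same per-allele effect as
moving from the middle to the highest. p-values use the two-sided normal
approximation (intended n ≫ 100). Degenerate (constant) dosage columns are
reported with beta 0, infinite se, p 1 rather than dropped, so row
alignment survives.

The stacked interaction analysis duplicates each individual (early and
adult measurements), fits
`category ~ dosage + time + dosage:time + covariates`, and reads the
adult-minus-early effect difference off the interaction term. Because the
two rows of an individual share noise, standard errors are CR1
cluster-robust sandwiches clustered on individual (plain OLS is available
behind a flag for comparison). Flags use the Bonferroni threshold
α / n_variants, returned exactly as α/n.

Instruments are variants with p < 5×10⁻⁸ after greedy LD clumping at
r² < 0.001: repeatedly take the smallest-p remaining variant, discard
everything with squared dosage correlation ≥ the ceiling against it. Ties
on p break lexicographically by variant id for reproducibility. r² is
composite LD computed on reference-panel dosages. For MVMR the two
exposures' clumped lists are merged (a shared variant keeps its smaller p)
and re-clumped jointly with the same rule.

### Winner's curse and the selection sample

Selecting instruments on the same scan whose betas are then used as the
exposure associations inflates the selected |β̂ₓ| (regression to the
mean), which attenuates downstream causal estimates — at the default
simulated sample sizes by roughly 1–4 % of the effect. Replicated
validation experiments therefore select instruments in a third,
independent sample (`n_selection`), which also serves as the external LD
reference for clumping; exposure betas entering the estimators come from
the untouched exposure sample. Single pipeline runs default to same-sample
selection, the usual situation when one discovery study doubles as the
exposure study.

## Estimators

* **Wald ratio** β̂_y/β̂_x with first-order se = se_y/|β̂_x|; the
  second-order form is available but off by default, consistent with the
  IVW weighting.
* **IVW** — fixed-effect: weighted regression through the origin with
  weights 1/se_y². A multiplicative random-effects option inflates the se
  by max(1, Q/df)^½ for sensitivity. Cochran's Q with n−1 df measures
  heterogeneity.
* **MR-Egger** — same regression with an intercept after orienting
  exposure betas non-negative; the intercept estimates directional
  pleiotropy. Constraining the intercept to zero reproduces IVW exactly
  (used as a cross-check).
* **MVMR** — weighted normal equations of outcome betas on the k exposure
  columns, no intercept. Exact, deterministic, and oracle-checkable; with
  k = 1 it coincides with IVW to machine precision. Instrument
  orientation is not forced — signs are handled by the joint regression.
* **Instrument strength** — marginal mean F is mean (β̂/se)² over
  instruments. Conditional F for exposure j regresses its beta column on
  the other exposures' columns (weights 1/se_{x_j}²) and scales the
  weighted residual sum of squares by n − k + 1; orthogonal strong
  instruments recover the marginal F, duplicated columns give ≈ 0.

Confidence intervals use the 1.96 normal quantile throughout; on binary
outcomes estimates exponentiate to odds ratios per category change. All
standard errors are first-order: they ignore exposure-beta uncertainty
(the standard convention), which undercovers slightly when exposure and
outcome samples are comparable in size — visible as ~92 % empirical
coverage in equal-n simulations. The framework's intended regime, an
exposure GWAS several times larger than the outcome study, restores near-
nominal coverage; the negative-control experiment uses a 2:1 ratio for
this reason, while the parameter-recovery experiment deliberately keeps
equal samples and documents its wider coverage band.

## Decomposition and scenario classification

indirect = total − direct, with the independence approximation
se = (se_total² + se_direct²)^½, labelled approximate because the two fits
share instruments (no bootstrap is attempted on summary data). The
scenario label is a reporting heuristic, not inference: *mediated* when
the direct CI covers 0 while the total CI excludes it; *direct-only* when
|indirect| < 0.2·|total| and the CIs overlap; *both* otherwise.

## Harmonization

Outcome (and co-exposure) statistics are aligned to the first exposure's
effect allele: swapped alleles negate the beta and complement the
frequency; mismatched pairs are dropped with a flag. Palindromic variants
(A/T, G/C) are dropped when any frequency lies in [0.42, 0.58] (a common
community default, exposed in config) and otherwise aligned by frequency
side. Flipping is an involution, and harmonizing scans generated from a
shared panel is lossless — both properties are tested. Variants missing
from the outcome are excluded and reported, not proxied.

## Score validation

Scores are Σ weight × dosage with discovery-scan betas as weights (the
weighting is configurable; unit weights optional). Validation cohorts are
independent draws from the same panel; each life stage's latent adiposity
is dichotomised strictly above its empirical 85th centile ("overweight"),
and tie-corrected rank (Mann–Whitney) AUCs compare the two scores. The
expected pattern — the early-variant score predicts childhood overweight
better, the adult-variant score adulthood overweight — held in 100 of 100
replicates at default settings.

## Misclassification study

The default grid crosses misclassification {none, 10 % symmetric
nondifferential, differential with slope 0.4 per adult-latent unit —
about a ten-percentage-point reporting shift across the adult
interquartile range} with early-life direct effects {0, +0.3, −0.3}
(adult direct effect +0.3, mediation 0.6, per-allele effect sd 0.2 so
selection retains most causal variants). These magnitudes are stand-ins
chosen for detectability at desk scale — the original simulation's
parameters are not public — and are all overridable; cells record their
settings in the output.

Study scenarios put the outcome on the **category** scale and scan the
categorical measurements, because then the per-category path coefficients
are exactly the estimators' probability limits under error-free
reporting: each variant's outcome association is, by linearity of
covariance, the same linear combination of its category associations. The
univariable total effect converges to
$\beta_{ED} + \beta_{AD}\,\theta\,s_A/s_E$ where $s = (\phi(z_1)+\phi(z_2))/\sigma_L$
is the category-on-latent regression slope of a Gaussian latent cut at
the standard-normal quantiles $z$ of the category proportions (Stein's
identity); the latent SDs come term-by-term from the scenario, so each
replicate's estimand is computed analytically from its own panel, with a
large-cohort empirical estimate kept as an independent cross-check.

Per replicate the full pipeline runs with misclassification applied to
every sample that scans the reported measure; replicates with too few
surviving instruments are excluded and counted. Replicate seeds derive
from the grid seed by a counter (`seed·1000003 + crc32(cell) + rep`,
mod 2³¹), so any cell is independently re-runnable. The direction report
flags quadrants of {differential?, early effect?} whose adult-direct bias
exceeds 3 Monte-Carlo SEs and states whether the bias sign flips between
opposed-effect cells. At defaults the study reproduces the expected truth
table: early instrument strength attenuates under any misclassification;
the adult direct effect is biased only under differential misreporting
combined with a real early-life effect; and that bias flips sign with the
relative direction of the two effects.

## Problem sizes and numerical choices

Replicated experiments default to 100-variant panels with 20 000
individuals per sample (40 000 exposure-side for the negative control):
200 replicates for parameter recovery, 100 for classification, negative
control and score separation, 30 per misclassification cell — sizes at
which each experiment completes in a few minutes on one CPU while Monte-
Carlo error stays well below the effects being measured. Calibration uses
2 000 null variants and direct summary-statistic simulation for Cochran's
Q (exactly chi-square under homogeneity). RNG streams are
`numpy.random.default_rng` seed sequences keyed by scenario seed and
sample label, so exposure/outcome/selection arms are independent and every
result is bit-reproducible.

## What the generator does not emulate

Simulated individuals are unrelated with no population structure, so
per-variant least squares is the correct scan; mixed-model association,
relatedness and stratification artefacts are out of scope. LD is
block-equicorrelated, not drawn from real haplotype maps; there is no
imputation uncertainty, missingness, X-chromosome dosage model,
assortative mating or dynastic effect. Palindromic alleles are disabled by
default (an option enables them to exercise the harmonization policy), so
strand ambiguity in the wild is only partially represented. Binary
outcomes use a logistic model whose non-collapsibility prevents exact
path-product recovery; parameter-recovery claims therefore use continuous
outcomes, and binary runs are checked for sign and null behaviour only.
Passing tests show the machinery is correct under these assumptions, not
that any particular real-data estimate is unbiased.
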