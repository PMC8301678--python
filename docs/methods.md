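# Methods

## The morphotype test as a diagnostic test

Two hybridizing mussel species are distinguished by a binary shell
character whose state frequencies differ between species.  Individuals are
assigned to a genotype group by their admixture proportion q (the estimated
fraction of *M. trossulus* genes): trossulus if q > 0.5, edulis otherwise,
with the boundary inclusive to edulis.  Each group contains purebreds and
hybrids; the pipeline deliberately has no separate hybrid class in its 2×2
tables, mirroring how the groups are used downstream.

For a sample, the 2×2 genotype-by-morphotype table yields the prevalence
`Ptros`, the morphotype frequency `PT`, and the four clinical indices:
sensitivity `P(T|tros)`, false-positive rate `P(T|edu)` (= 1 −
specificity), positive predictive value `P(tros|T)` and negative predictive
value `P(edu|E)`.  Indices with empty denominators (no trossulus in the
sample, no T-morphotypes, …) are *undefined* and carried as `None`/NaN with
explicit flags — never as zero — so degenerate samples cannot bias pooled
analyses.  Pooling across samples sums the 2×2 counts.

Two exact identities connect the counting and formula layers and are
enforced by property tests: `PT = Ptros·sens + (1−Ptros)·fpr` on every
table, and equality of the counted PPV/NPV with the Bayes formulas
evaluated at the same sample's (sens, fpr, Ptros).

### A note on the NPV formula

The printed form of the negative-predictive-value equation in the source
material repeats the false-positive-rate factor in the second term of the
denominator.  That form cannot reproduce its own worked example
(0.96×0.5 / (1−0.39) = 0.787); the Bayes-consistent form with
`(1 − P(T|tros))` does.  This package implements the Bayes-consistent form
throughout:

```
NPV(p) = (1−p)(1−fpr) / [(1−p)(1−fpr) + p(1−sens)]
```

### Prevalence from morphotype frequency

`Ptros = (PT − fpr)/(sens − fpr)` requires an informative marker
(`sens > fpr`; violations raise).  Observed PT outside the attainable band
`[fpr, sens]` is clamped to the nearest pure population; the unclamped
solution is available for diagnostics.

## Published regional formulas

The region-specific logistic formulas (five sets — WSBL, BH, GOM, BALT,
NORW — × three targets: prevalence-from-PT and the two correctness curves)
ship in `data/published_models.csv` to their printed one-decimal precision.
Because the coefficients are rounded, predictions at an equal mixture match
their printed two-decimal counterparts only to ±0.02 (e.g. the NORW
T-morphotype value lands exactly at that bound); tests compare at that
tolerance and treat it as inclusive.

## Regression models

All six model structures are individual-level logistic regressions:

| id | response (1 =) | fixed predictors | random |
|----|----------------|------------------|--------|
| M1 | T-morphotype | Ptros × Set | — |
| M4 | trossulus genotype | PT × Set | — |
| M2/M5 | T-morphotype | Ptros × Species × Set | sample |
| M3/M6 | correct identification | Ptros × Morphotype × Set | sample |

"Correct identification" codes trossulus-as-T and edulis-as-E as 1.  Set
terms drop automatically for single-set data, and a `by_level`
parametrization (separate intercept and slope per morphotype) makes M6
coefficients directly comparable to the published per-morphotype formulas.
Sample-level covariates are the observed per-sample frequencies by default;
simulation studies may supply design values instead (`covariates=
"provided"`), which is what the parameter-recovery tests do — recovery
against the generating covariate is the well-posed experiment, while
empirical-frequency fits are what the pipeline does on field data.

### Estimation

Mixed models (random sample intercept) are fitted by maximum likelihood
with adaptive Gauss–Hermite quadrature: with a single scalar random effect
the marginal likelihood factorises over samples into one-dimensional
integrals, each centred at its Laplace mode and scaled by the local
curvature (1 quadrature node reproduces the Laplace approximation; the
default is 15 nodes).  The fitter is validated against lme4's `glmer`
(nAGQ = 25) on identical data, agreeing in coefficients, random-intercept
SD and log-likelihood to ~1e-3.  Standard errors come from the numerically
differentiated observed information; AIC is `2k − 2·loglik` with the
random-effect SD counted as a parameter, and model comparisons are made
only between fits to the identical response vector (the set-pooling test
refits the same M3 structure under each candidate grouping of geographic
sets and selects the AIC minimum).

Fixed-effect-only models use a binomial GLM.  Complete or quasi-complete
separation — routine in pure samples at prevalence extremes — is detected
(diverging estimates or standard errors) and handled by Firth's
bias-reduced logistic regression (Jeffreys penalty), flagged in the output.
Rank-deficient designs are rejected naming an aliased term.

Pseudo-R² follows the logit-scale variance decomposition: marginal
`σ²f/(σ²f+σ²α+π²/3)` and conditional `(σ²f+σ²α)/(σ²f+σ²α+π²/3)`, where σ²f
is the variance of the fixed-effect linear predictor over the data and
π²/3 the theoretical logistic residual variance.  Prediction intervals are
Wald intervals on the linear predictor mapped through the inverse logit, so
bounds respect [0, 1].

## Calibration-pair experiment

Applying the calculators in an unstudied contact zone needs operating
characteristics from a few genotyped "calibration" samples.  The pair
search evaluates every unordered pair: pooled 2×2 counts give candidate
(sens, fpr); the candidate calculator curves are compared with reference
regression curves over the frequency grid [0, 1] in steps of 0.01
(endpoints included, unweighted mean squared difference, `Goodness =
1/MSS`, an exact match reported as an infinity sentinel that is plotted but
never smoothed).  The prevalence target compares the linear
prevalence-equation predictions against a prevalence-from-PT reference (a
fitted M4 or a published formula); the
predictive target pools the squared deviations of the PPV and NPV curves
against a correctness-model reference with equal weight.  Pairs whose
pooled counts cannot yield usable parameters (a species absent, or
sens ≤ fpr) are recorded as failed rather than dropped.

The predictive-target curves are evaluated directly on the prevalence grid.
The alternative — feeding the predictive-value formulas with prevalences
back-calculated through the prevalence equation — was implemented and
tested during development: it makes predictive
goodness increase monotonically with pair dissimilarity, which contradicts
the empirically established selection rule, so the direct-grid reading was
adopted.

LOESS summaries use an in-package tricube local-polynomial smoother
(default span 0.75, local quadratic, no robustness iterations); the
smoother is deterministic and permutation-invariant.

The selection rules are implemented as prevalence strata: prevalence
calibration pools samples with `Ptros < 0.1` or `> 0.8`; predictive
calibration pools `0.45 < Ptros < 0.65`.  An empty stratum raises an error
naming the stratum — the cue to fall back to pooling all samples in
data-poor regions.

Note a geometric property of the dissimilarity index used when reading
band summaries: `Delta(0.5, p) = 0.5` for *any* p, so pairs containing a
balanced sample sit exactly on the 0.25–0.5 band boundary; the mixed band
is therefore treated as closed, and the selection-rule tests locate the
optimum with the LOESS curve's argmax as well as band medians.

## Size-association screen

One logistic fit of morphotype on shell length per (sample × species) cell
that is *informative* — both morphotypes present, at least three mussels,
length varying.  Non-informative cells are flagged and excluded from
testing.  Hochberg's step-up correction is applied within each species'
family of informative cells (the two species are corrected separately);
the implementation is checked against both a brute-force evaluation of the
step-up definition and an independent library implementation.  The
complementary check regresses deviance residuals of the fitted correctness
model (fixed-effect fitted probabilities) on length and flags any
significant trend.

## Synthetic data generator

The generator emulates the statistical structure of hybrid-zone samples;
every distributional choice is exposed in `SimulationConfig`.

* **Admixture proportions.**  A three-component mixture: purebred edulis
  `q = 0.2·Beta(1, c)`, purebred trossulus mirrored at 1, hybrids on
  (0.2, 0.8) at `q = 0.5 ± 0.3·Beta(1.2, 1.2)`.  The purebred
  concentration c (default 5) is a free dispersion knob — the within-
  purebred spread of q is not constrained by any published value.  The
  hybrid side is drawn Bernoulli(target prevalence), which makes the
  expected fraction of q > 0.5 genotypes equal the target exactly across
  the whole [0, 1] range; a symmetric hybrid component would bias the
  prevalence near the endpoints.  The `bimodal` regime (10% hybrids)
  mirrors most contact zones; `flattened` (35%) mirrors heavily
  introgressed ones.  Setting the hybrid fraction to zero gives strictly
  bimodal q (the purebred components have bounded support).
* **Morphotypes.**  `P(T | species) = invlogit(intercept_species +
  slope_species · prevalence)`; hybrids use the midpoint of the two
  species' linear predictors (hybrids are intermediate in morphotype
  frequency).  Defaults: intercepts logit(0.74)/logit(0.04), slopes 0 —
  the prevalence-independence assumption of the plain calculators.
* **Shell lengths.**  Log-normal (median 35 mm, log-SD 0.3) with an
  optional morphotype–size effect (logit shift per mm, default 0 = the
  no-size-effect null).
* **Reproducibility.**  One integer seed; per-sample substreams are
  spawned from it keyed by sample index, so identical configurations give
  byte-identical tables and any sample can be regenerated alone.

### The mosaic-zone preset

`wsbl_like_config()` encodes a 36-sample study emulating a recently
invaded, mostly edulis-dominated mosaic contact zone: 18 near-pure-edulis
sites (prevalence 0–0.10), 10 mixing-front samples (0.28–0.47) and 8
near-pure-trossulus patches (0.93–1.0), with per-sample sizes uniform on
[18, 173].  Morphotype drift (intercepts 0.41/−4.5, slopes 1.7/2.3 on the
logit scale) was calibrated against the *published* regional curves by a
noise-free expectation calculation: it places the effective operating
characteristics of well-mixed populations at the optimum implied by those
curves (≈0.73 sensitivity, ≈0.05 false-positive rate at a balanced mix,
rising to ≈0.85 / falling to ≈0.02 in pure populations).  Under these
conditions the pair search reproduces the established selection rules:
prevalence calibration is best with the most dissimilar pairs, predictive
calibration with mixed pairs.  The bimodal sample-prevalence distribution
matters here: a uniform grid would create asymmetric mixed-with-high pairs
that do not exist in mosaic field collections and that blur the contrast
between the two rules.

### What the generator does not emulate

No genetic linkage or explicit multi-locus genotypes, no spatial structure,
no environmental (e.g. salinity) covariates of morphotype expression, no
scoring error in the morphotype itself, and no sample-level random
morphotype heterogeneity beyond the prevalence drift.  Passing tests
therefore demonstrate the internal consistency of the estimators and the
qualitative selection rules under the assumed structure — not the field
accuracy of the morphotype test in any particular zone.

## Problem sizes used in the test suite

Monte-Carlo checks of the calculators count 10⁶ simulated individuals per
prevalence; coefficient recovery runs 100 replicates of a 36-sample ×
100-individual study per model structure; the calibration selection rules
pool 630-pair searches over 20 simulated studies; large-n convergence
checks use 10⁴–10⁵ individuals.  These sizes give Monte-Carlo errors an
order of magnitude below the tolerances asserted.

## Known limitations

* GLMM standard errors are Wald-type from numeric observed information;
  near-boundary random-effect variances (σ → 0) make the σ component of
  the covariance unreliable (fixed effects are unaffected; the reported
  fits flag convergence).
* The published coefficients are one-decimal; exact reproduction of the
  source's fitted models is impossible in principle, and the regional
  fitted coefficients for the species-conditional drift models are not
  public — the generator's drift is a calibrated emulation, not a
  reconstruction.
* The Firth fallback reports penalised-likelihood values; its AIC is not
  comparable with plain-ML fits.
* Confidence propagation from calibration-sample counting error into the
  prevalence estimates is out of scope; reported parameters carry
  provenance labels instead.
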