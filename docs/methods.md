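# Methods

## The model

`atlascomp` estimates how immune cell composition (and the two-category
immune/non-immune cellularity case) varies with covariates such as age, sex,
ethnicity and assay technology across a hierarchically structured cell atlas:
cells belong to samples, samples to datasets (studies), datasets to tissues.

For sample *s* with total cell count *n_s* and categories *k = 1..K*, each
category count is modelled as beta-binomial,

    y_{s,k} ~ BetaBinomial(n_s, mu_{s,k} * phi_{s,k}, (1 - mu_{s,k}) * phi_{s,k})

with a softmax-linked mean and a log-linear precision:

    mu_{s,k}  = softmax_k( x_s' beta_k + z_s' u_{tissue(s),k} + v_{dataset(s),k} )
    phi_{s,k} = exp( xv_s' (gamma0 + Gamma_k) )

* `beta` — population-level (fixed) coefficients, one row per covariate.
  Body-level hypotheses are tested on `beta` alone.
* `u`, `v` — group-level (random) coefficients: tissues receive partially
  pooled intercepts and age slopes, datasets partially pooled intercepts.
  Tissue-level hypotheses are tested on the sum `beta + u_tissue`.
* `Gamma` — category-specific variability coefficients; `gamma0` is the
  category-wide baseline log-precision per variability covariate. A fully
  sum-to-zero precision row would pin the geometric-mean precision to one,
  so the baseline is kept as a separate scalar.

Identifiability across categories is fixed by a sum-to-zero constraint
rather than a pinned reference category, so intercept-free (cell-means)
designs — used for ethnicity contrasts — stay symmetric. Every coefficient
row is parametrised in an orthonormal basis of the sum-to-zero subspace, so
the constraint holds exactly on every posterior draw.

The multilevel structure is what makes body-level claims meaningful on
atlas data: single-level fits would be dominated by over-represented
tissues (blood), and non-overlapping age ranges across tissues invite
Simpson's-paradox reversals that tissue-level random slopes absorb.

## Priors and inference

* `beta` entries: Normal(0, 2). Variability rows: Normal(0, 1); baseline
  log-precision: Normal(3, 3) (precision ~ e^3 ≈ 20 a priori).
* Group-level coefficients use the non-centred parametrisation
  `u = sigma * u_raw`, `u_raw ~ Normal(0, 1)`, with a lognormal prior on
  each per-covariate scale (`log sigma ~ Normal(log 0.3, 0.8)`). Both
  choices are deliberate: the centred joint mode degenerates (the Gaussian
  normaliser drags `log sigma` to minus infinity whenever a group variance
  is near zero), and any scale prior with positive density at zero lets the
  mode fall into the hierarchical funnel spike.
* Mean-variability association: the precision intercept row is tied to the
  abundance intercept row through
  `Gamma_{0,k} ~ Normal(c0 + c1 * beta_{0,k}, tau)`, with
  `c0, c1 ~ Normal(0, 1)` and `log tau ~ Normal(log 0.3, 0.5)`. This
  hierarchical prior is this package's stand-in for the mean-variability
  association of compositional single-cell models; its exact form is a
  documented approximation.

Two inference backends share one analytic log-posterior gradient:

* **`laplace`** (default): L-BFGS with restarts finds the joint mode; a
  Newton polish using the finite-difference Hessian finishes the nearly
  flat directions (the likelihood only pins `beta + mean(u)`; the split is
  prior-determined and poorly conditioned for quasi-Newton methods alone).
  Draws come from the Gaussian approximation N(mode, H^-1). This mode is
  approximate — it understates skew and funnel geometry — but
  simulation-based calibration of the age slope (50 prior-draw replicates,
  K=4, 50 samples) shows no detectable rank-uniformity violation, and it is
  fast enough for the standing simulation suites.
* **`hmc`**: a hand-written adaptive Hamiltonian Monte Carlo sampler
  (dual-averaging step size, diagonal mass matrix from warmup, jittered
  path length), 4 chains by default. Used as a cross-check; split-Rhat,
  effective sample size and divergence counts are reported for both modes.

## Hypothesis testing

Effects are tested against an interval null on the log-ratio scale:
`prob_null = P(|theta| < null_halfwidth)` with `null_halfwidth = 0.2` by
default (the threshold is a flag; only the FDR level 0.05 is fixed by
convention). Categories are ranked by `prob_null` and the FDR at rank *i*
is the mean of the *i* smallest values — the posterior-probability FDR.
The "other immune" consensus fallback category is carried through the model
but never tested: it is reported with no FDR and can never be significant.

Signed fold changes summarise effects on the proportion scale: predicted
proportions at the two limits of the covariate range (all else at
baseline), reported as `p_hi / p_lo` when increasing and `-(p_lo / p_hi)`
when decreasing.

## Outlier handling

An observation is flagged when its mid-p probability-integral transform
under the plug-in beta-binomial predictive (posterior-mean linear
predictors) falls in either tail beyond `(1 - ppc_level)/2`; the analytic
CDF is used rather than sampled predictive quantiles because Gaussian tail
draws of the scale parameters corrupt a sampled mixture badly enough to
halve detection sensitivity. With `outlier_passes > 1`, only decisively
incompatible observations (exclusion level 0.995) are masked before the
refit — excluding merely borderline observations truncates the sampling
distribution and biases the refitted coefficients — and reported flags are
recomputed against the cleaned refit at the nominal `ppc_level` (0.95),
since the first pass's dispersion estimate is inflated by the very outliers
being hunted.

## Removal of unwanted variation

Residuals are computed on the link scale: centred log-ratio of the observed
proportions (pseudo-count 0.5) minus the posterior-mean full-model linear
predictor. The target model's predictor (any subset of fixed terms and
random groupings) plus those residuals, pushed through softmax, gives
adjusted proportions that are strictly positive and sum to one. Targeting
everything reproduces the observed (pseudo-counted) proportions exactly —
a useful identity check. The deterministic posterior-mean predictor is used
rather than posterior-predictive draws so no sampling noise enters the
adjusted data.

## Ageing trajectories

The trajectory model is `composition ~ age + (age | tissue)` plus dataset
intercepts. Tissue-level compositions are predicted on an age grid of 10 to
90 years in steps of 10 (ages converted to the cohort's z-scored age
covariate), the proportions are moved to the per-category logit scale
(clipped at 1e-6), and a centred, unscaled PCA is run on the grid.
Per-category logit is used literally, with the centred log-ratio available
behind a flag, because logit of a composition is not closure-respecting but
is the conventional visualisation scale. Loadings are reported per
component with a top-10 helper.

## Cell-communication model

Upstream ligand-receptor scoring yields per-sample pairwise weights in
(0, 1). Eligibility: cell types with fewer than ten cells in a sample are
dropped, then samples with fewer than two remaining immune cell types
(boundary semantics inclusive: exactly ten cells and exactly two types are
kept). A cell type's overall strength is the mean of its outgoing pairwise
weights per axis. Age effects are fitted per (tissue, cell type, axis) with
a multilevel beta regression: `weight ~ Beta(mu * kappa, (1-mu) * kappa)`,
`logit(mu) = alpha + beta_age * age_scaled + b_dataset`, constant precision
`kappa` (no variability regression is specified for this analysis), and
dataset random intercepts with the same non-centred/lognormal treatment as
the main model. An effect is flagged when its 95% credible interval
excludes zero. A pooled cross-tissue mode exists behind a flag since the
grouping structure for this model is not fully pinned down.

## Harmonisation conventions

* Ages are stored in days; one year is exactly 365 days. Stage strings map
  through an editable fixture (adolescent → 15 years = 5475 days).
* Consensus over up to four annotation sources: tier 1 — all agree; tier
  2/3 — one/two disagree; tier 4 — no two agree, labelled "other immune".
  Tiers count disagreements among *observed* sources only; missing sources
  do not inflate the tier. Two-two ties are broken by fixed source
  priority, original study annotation first (configurable).
* Cohort filters are applied in a fixed order with per-rule attrition
  logging; every excluded sample is attributed to the first rule that
  triggers. Age scaling is z-score standardisation on the retained cohort.
  The lymphoid-tissue list for the cellularity analyses is a configurable
  fixture {blood, lymph node, spleen, thymus, bone marrow}. The
  high-confidence composition filter keeps tiers 1-3 by default;
  `composition_tiers=(1,2,3,4)` carries "other immune" as its own category
  (reported, never tested).
* The dataset-replication filter defaults to "at least 3 samples per
  dataset" for both modes; the stricter composition-mode variant is exposed
  as configuration because its exact form is ambiguous.

## The synthetic atlas

The generator emulates the features the analysis relies on: tissues ⊃
datasets ⊃ samples ⊃ cells; a configurable fraction of multi-tissue
datasets (default 0.262); tissue-specific age ranges (uniform in days);
categorical sex/ethnicity/technology frequencies; sum-constrained
overdispersed counts drawn as independent renormalised Beta proportions
followed by a multinomial (the generative counterpart of the fitted
beta-binomial; a Dirichlet-multinomial switch exists for robustness
checks); outlier contamination with recorded flags; four-source annotation
noise with a controlled consensus-tier distribution (default 87/5/5/3);
and Beta-distributed communication weights with sender-specific age slopes.

Default magnitudes, chosen once as plausible for atlas data and not
revisited: category intercept scale 1.0, covariate slope scale 0.75,
tissue intercept/slope sds 0.5/0.25, dataset intercept sd 0.3, baseline
log-precision 4 (phi ≈ 55). The relative size of dataset- versus
tissue-level variance components is not empirically anchored; the defaults
make no claim of realism and are exposed as configuration.

The generator does **not** simulate gene expression, doublets, ambient
RNA, spatial structure, or annotation noise correlated with cell identity.
Passing recovery and calibration suites therefore demonstrates correctness
of the machinery under the stated generative assumptions, not performance
on real atlas data.

## Problem sizes of the standing suites

Recovery: 20 seeds, K=4, 10 tissues, 2 datasets each, 200 samples,
200-1000 cells per sample, body-level age slope 1.0. FDR calibration: 20
seeds, K=20, 100 samples, all age effects zero. Outlier robustness: the
recovery conditions with 5% of entries scaled four-fold up or down; paired
error comparisons use the realized body-level slope (generating slope plus
the mean of the drawn tissue deviations) so they isolate the outlier
effect from tissue-sampling noise shared by both passes. Batch removal:
K=5, 20 datasets of 10 samples, dataset sd 0.5. Trajectories: K=6, 10
tissues sharing one age direction (norm 1.5) with identical baselines, 400
samples. Communication: 100 samples, 5 datasets, slope -1.0 on the logit
scale. Simulation-based calibration: 50 replicates, K=4, 50 samples,
fixed-effects design with priors matched between generator and fit.

## Known limitations

* The Laplace posterior is a Gaussian approximation; credible intervals for
  scale hyperparameters are symmetric on the log scale and can understate
  tail mass. Use the HMC mode when interval calibration of the hierarchy
  itself matters.
* The beta-binomial per-category likelihood is a composite (marginal)
  likelihood: category counts against the sample total are not jointly
  generative, which is why simulation-based calibration is approximate by
  construction.
* Age enters linearly on the log-ratio scale; non-linear (spline) age
  effects, zero-inflation and tree-structured priors over cell types are
  out of scope.
* MAP-based scale estimation under the lognormal prior cannot shrink a
  group variance entirely to zero; with truly zero group variance a small
  residual pooling noise remains (bounded by the prior's lower range).
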