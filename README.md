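# atlascomp

Multilevel Bayesian compositional analysis for cell atlases: estimate how
immune cell composition and cellularity change with age, sex, ethnicity and
technology across a hierarchy of tissues, datasets (studies) and samples,
and do so robustly on data that no one designed as a single experiment.

Atlas-scale single-cell resources aggregate hundreds of studies with wildly
uneven coverage: blood alone can contribute a quarter of all samples, age
ranges differ per tissue, and annotations follow study-specific vocabulary.
A single-level model fitted to such data is dominated by over-represented
tissues and invites Simpson's-paradox reversals. `atlascomp` addresses this
with a multilevel beta-binomial model of category counts,

    y_{s,k} ~ BetaBinomial(n_s, mu_{s,k} phi_{s,k}, (1 - mu_{s,k}) phi_{s,k})
    mu_{s,k}  = softmax_k( x_s' beta_k + z_s' u_{tissue(s),k} + v_{dataset(s),k} )
    phi_{s,k} = exp( xv_s' gamma_k )

where body-level claims test the population coefficients `beta` alone and
tissue-level claims test `beta + u_tissue`. Significance uses the
posterior-probability false-discovery rate: categories ranked by the
posterior mass inside an interval null, FDR at rank *i* equal to the mean of
the *i* smallest null probabilities, thresholded at 0.05.

The package covers the full workflow:

| module | what it does |
| --- | --- |
| `atlascomp.synthetic_atlas` | hierarchical atlas generator with recorded ground truth |
| `atlascomp.harmonise` | age/tissue/sample-id harmonisation, consensus annotation tiers, cohort filters with attrition logging |
| `atlascomp.design` | fixed/variability/group-level design matrices, interactions, confounding checks |
| `atlascomp.multilevel` | model fitting (Laplace or HMC), outlier-robust refits, body/tissue tests, signed fold changes, prediction |
| `atlascomp.adjusted_views` | removal of unwanted variation via link-scale residuals; ageing-trajectory PCA |
| `atlascomp.communication` | cell-communication eligibility filters, strength summaries, multilevel beta regression on weights |
| `atlascomp.pipeline` / CLI | config-driven end-to-end runs with a provenance manifest |

## Worked example

The numbered scripts under `analysis/` run the whole story on a synthetic
atlas with known truth (10 tissues, 20 datasets, 200 samples, a body-level
age slope of 1.0 on the log-ratio scale for `type_0`):

```bash
python analysis/01_simulate_atlas.py
python analysis/02_build_cohort.py
python analysis/03_fit_composition.py
```

which prints, among other things:

```
body-level age effects:
category  posterior_mean  ci_lower  ci_upper  prob_null      fdr  significant
  type_0        0.970843  0.384646  1.570918     0.0055 0.005500         True
  type_1       -0.350899 -0.921634  0.265252     0.2785 0.183667        False
  type_2       -0.368945 -0.963230  0.202939     0.2670 0.136250        False
  type_3       -0.250999 -0.860594  0.367303     0.3620 0.228250        False

recovered slope [ 0.971 -0.351 -0.369 -0.251] vs truth [ 1.    -0.333 -0.333 -0.333] (MAE 0.041)
signed fold changes over the observed age range:
type_0    13.15
```

Only the category with a real age effect is called significant; its
posterior mean sits within 0.03 of the generating slope, and the signed
fold change says its share grows ~13-fold across the observed age range.
Scripts `04` and `05` continue with batch-adjusted proportions, the
10-to-90-year trajectory PCA, and the communication-strength beta model.

A minimal library session:

```python
from atlascomp import synthetic_atlas as sa, multilevel as ml
from atlascomp.design import DesignSpec, build_design

cfg = sa.AtlasConfig(n_tissues=4, datasets_per_tissue=2, samples_per_dataset=10)
samples = sa.generate_sample_frame(cfg, seed=0)
truth = sa.GroundTruth.random(4, 4, samples["dataset_id"].nunique(), seed=0)
counts = sa.generate_counts(samples, truth, DesignSpec(), seed=0)

fit = ml.fit(counts, build_design(samples, DesignSpec()),
             options=ml.FitOptions(seed=0))
effects = ml.test_effects(fit, "age_scaled", level="body")
```

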