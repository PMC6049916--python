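# Methods

## The cell-type index

Bulk expression profiles from macro-dissected brain tissue confound two
signals: per-cell regulation of individual genes, and shifts in the relative
abundance (or overall transcriptional output) of the cell populations that
make up the tissue. The cell-type index summarizes the second signal. For a
normalized, log2-scale matrix X (transcripts × samples):

1. **Row standardization.** Each transcript row is centered and scaled
   across samples (mean 0, sd 1, sample sd with the n−1 denominator), so
   transcripts with large dynamic range cannot dominate. Rows with zero
   variance carry no relative information and are dropped (a sd below
   1e−12 × the row's magnitude is treated as zero — float noise on a
   constant row otherwise survives and is amplified into pure noise by the
   scaling).
2. **Gene collapse.** Rows mapping to the same gene symbol (matching is
   case-insensitive; symbols are uppercased at load) are averaged per
   sample and the averaged row is re-standardized. We read the second
   rescale as a second z-score; nothing downstream depends on the
   distinction for single-probe genes.
3. **Publication indices.** For each signature set — the unique genes one
   reference publication claims as specific to one cell type — the index of
   a sample is the mean z-value over the matched genes. Sets matching fewer
   than `min_genes` genes (default 3, hard floor 1) are omitted with a
   warning: an "index" backed by one gene is just that gene's z-score.
4. **Consolidated indices.** Publication indices are recomputed on
   signature sets with *cross-category* genes removed (genes claimed by ≥2
   distinct primary categories; a gene claimed twice within one category is
   replication, not ambiguity), then averaged — as columns, not as pooled
   gene lists — within each of the ten primary categories. Publication
   indices reported to the user are computed on the full sets; overlap
   removal applies only to consolidation, where categories compete.

Because every ingredient is a mean of mean-zero unit-sd rows, every index
column has mean exactly 0 across samples and sd in (0, 1], and the whole
pipeline is invariant to per-gene positive affine transformations of the
input. An index is a *relative* quantity within one dataset; it is not an
absolute cell proportion and is not comparable across datasets in absolute
terms.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_genes` | 3 | minimum matched genes for a usable signature set |
| `excluded_tags` | none | exclusion profile; `config/exclusions.yaml` documents a "v2" slot for users who wish to drop weak sets |
| `missing_policy` | `drop` | rows with missing values are dropped; `impute` mean-fills per row before standardization |
| `remove_cross_category` | true | apply overlap removal during consolidation |

## The synthetic-data generator

The generator reproduces the physics the method assumes: cells mix
*linearly* in transcript space, but we observe log2(x+1) plus Gaussian
measurement noise (sd `noise_sd`, default 0.3 on the log2 scale — a typical
residual sd for normalized microarray data).

* **Profiles.** Gene baselines are log-normal (ln-mean 4, ln-sd 1; median
  ≈55 linear units). Each simulated type gets a disjoint block of marker
  genes whose mean in their own type is `fold` × baseline. The default
  `fold = 4` is typical of curated marker enrichments and keeps
  log2-observed signal approximately linear in the mixing proportion — the
  regime in which a z-score-averaging index is a sensible composition
  estimator. (At much larger folds the log2 curvature alone drives the
  index–proportion R² below ~0.95 even without noise.)
* **Mixtures.** A design matrix of simplex rows; expected linear expression
  is the proportion-weighted average of the type profiles.
* **Cohorts.** Covariates are drawn from distributions modeled on
  post-mortem psychiatric cohorts (pH ≈ N(6.7, 0.25); agonal factor 0–4
  skewed toward 0; PMI ≈ N(24 h, 8 h); age ≈ N(50, 15) clipped to 18–90;
  sex 35/65 F/M; diagnosis CTRL/MDD/BP/SCHIZ at 45/26/15/14%; three
  batches; rare exsanguination; a standardized RNA-degradation score).
  Per-sample composition is softmax over per-type log-odds: a fixed base
  (chosen to mimic a plausible cortical mix), plus N(0, `logodds_sd`)
  per-sample heterogeneity, plus covariate effects. Effects apply to
  internally standardized numeric covariates and to 0/1 indicators for
  categorical levels (keyed `covariate:level`), so a log-odds shift of 0.5
  means the same thing for age as for a diagnosis indicator.
  `logodds_sd = 0.5` by default: real macro-dissected tissue shows large
  natural composition variance (dissection, anatomy), and without it the
  composition would be a deterministic function of the covariates, making
  cell indices exactly collinear with covariates in composition-adjusted
  models.
* **Synthetic marker database.** Each type's markers are split round-robin
  into `pubs_per_type` publication tags; a chosen number of markers is
  additionally listed under a second category to exercise overlap removal.

All randomness flows from one integer seed through `numpy.random`
SeedSequence spawning, so every artifact is bit-reproducible.

What the generator does **not** emulate: probe cross-hybridization, 3' bias
and RNA-degradation curves, platform batch artifacts, count noise in
RNA-Seq, correlated marker co-expression within a cell type beyond the
shared composition factor, and marker sets that are wrong or partially
non-specific. Passing the simulation suite therefore demonstrates internal
correctness and statistical calibration under the stated model — not that
curated marker lists are accurate for any particular real dataset.

### The packaged reference-table stand-in

`blendr.synthetic_reference` deterministically builds a *synthetic*
stand-in for the curated marker spreadsheet with the same structure — 3383
rows, 2499 unique genes, 38 publication sets over the 10 categories, a
17-gene erythrocyte set, with realistic within-category replication and 60
cross-category overlap genes — under synthetic gene symbols. It exists so
structural behavior (loading, set derivation, overlap removal, .gmt export)
can be exercised at full scale without shipping curated third-party
content.

## Cohort statistics

* **Covariate scan.** One OLS model per cell-type index with all preset
  covariates entered simultaneously. Categorical terms are
  treatment-coded against declared references (diagnosis → CTRL, sex → F,
  batch → B1 by default). Three presets mirror common metadata
  availability: `eq1` (pH, agonal factor, PMI, age, sex, diagnosis,
  exsanguination), `eq2` (pH, PMI, age, sex, diagnosis, RNA degradation,
  batch when present), `eq3` (adds institution and manner of death).
  Missing covariate values are handled by listwise deletion with the
  retained n logged. BH adjustment is applied over the whole scan table.
* **Meta-analysis.** Fixed-effects inverse-variance pooling:
  b̂ = Σ(bᵢ/vᵢ)/Σ(1/vᵢ), SE = (Σ1/vᵢ)^(−1/2), z = b̂/SE with a normal
  reference — the standard fixed-effects convention.
* **BH adjustment** is the step-up rule q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j capped at
  1. It is order-preserving and never below p, but it is *not* idempotent
  in general (p = (0.1, 0.9) adjusts to (0.2, 0.9); re-adjusting gives
  (0.4, 0.9)); tests assert the true properties.
* **Welch's t** uses the unequal-variance statistic with
  Welch–Satterthwaite degrees of freedom. **Cohen's d** uses the classic
  pooled sd, √(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)); the average-sd variant
  differs for unbalanced groups and is not provided.
* **PCA association** centers transcript rows, decomposes by SVD, and
  reports per-PC % variance plus the simple-regression R² of each PC score
  on each index column (and on named index combinations, e.g. the
  astrocyte/endothelial average). A flag recomputes the PCA with all
  database genes excluded, to show composition signal is not an artifact of
  the marker genes themselves being highly variable.

## Differential-expression model comparison

Per gene, five nested OLS models: M1 diagnosis only; M2 + traditional
covariates; M3 diagnosis + the five prevalent cell indices (astrocyte,
microglia, oligodendrocyte, interneuron, projection neuron — the reduced
set avoids the multicollinearity of all ten); M4 = M2 + prevalent indices;
M5 = M2 + all ten. All five are fitted on the same listwise-complete sample
set so information criteria are comparable; AIC/BIC use the full Gaussian
log-likelihood including constants. Diagnosis enters as one factor with all
levels and the requested contrast's coefficient is extracted — not
per-diagnosis subset models. Fits are plain OLS (no empirical-Bayes
moderation of variances), vectorized across genes because the design matrix
is shared; a per-gene statsmodels fit is the cross-check in the tests.
Genes with (numerically) zero residual variance are reported with t = 0,
p = 1 and flagged out of the fit summaries.

Replication against a reference list of previously documented effects uses
the direction of the fitted contrast and a nominal p < 0.05 detection
threshold; reference genes absent from the dataset leave the denominator.
Model contrasts on detection counts, and enrichment of significant genes in
a reference set versus the background, use the two-sided Fisher exact test
(probability-mass definition; conditional ML odds ratio). The repository
ships only a schema for reference lists plus synthetic stand-ins built by
the tests — not any curated list.

## Validation experiments and problem sizes

`blendr.experiments` packages the validation battery; `tests/` and
`scripts/acceptance.py` drive it:

* oracle equivalence of the full index pipeline against an independent
  loop reimplementation on 50 random 30×10 matrices (agreement to 1e−10);
* pure-type recovery: 10/10 noiseless; ≥90% mean accuracy at noise sd 0.5
  over 100 seeds;
* titration linearity: Spearman ρ = 1 and Pearson R² ≥ 0.95 on noiseless
  5-point two-type titrations;
* index invariants: column means 0 (±1e−8), sd ∈ (0,1], affine invariance;
* type-I error: 5% ± 2 false-positive rate over 500 null cohorts (n=200);
* effect recovery: a −0.5 log-odds astrocyte shift with MDD yields a
  negative fitted MDD coefficient on the Astrocyte index in ≥90% of 200
  seeds (n=150, noise 0.3);
* mediation: with a −0.8 composition effect, astrocyte marker genes
  significant under M2 are attenuated under M4, and per-gene-centered BIC
  favors M4 over M2, in ≥90% of 200 seeds.

Experiment sizes (120 genes, 8 markers/type) are the package's chosen desk
scale: large enough that each index rests on 8 disjoint markers, small
enough that the full battery runs in well under a minute.

## Known limitations

* Indices conflate cell abundance with per-cell transcriptional output; a
  higher index may mean more cells or more output per cell.
* Consolidation averages publication columns with equal weight regardless
  of set size or quality; a weak publication set dilutes its category.
* The covariate scan and DE models are ordinary least squares; no
  robust/moderated variants are provided.
* Real-data benchmarks (admixture microarrays, multi-region atlases,
  psychiatric cohorts) require external downloads and are out of scope for
  the test suite; the simulation battery is the shipped evidence.
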