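# Methods

## The model

`stf-twas` implements a transcriptome-wide association workflow that
restricts gene-expression prediction to genetic variants lying in
*susceptible TF-occupied cis-regulatory elements* (STFCREs): binding regions
of transcription factors whose occupancy is associated with inflation of
GWAS test statistics.

### Stage 1 — susceptible-TF screening

For every candidate TF, the per-variant GWAS chi-squared value is regressed
on binary occupancy with a Gaussian random intercept per LD block:

    Y_ij = β0 + β1 · TF_ij + V_i + ε_ij,   V_i ~ N(0, σ_b²),  ε_ij ~ N(0, σ_e²)

where `Y_ij` is the chi-squared value of variant *j* in LD block *i* and
`TF_ij ∈ {0, 1}` its occupancy.  `β1` is interpretable as the mean
chi-squared difference between occupancy states (Δχ̄²); the random intercept
absorbs the shared association level of a block, handling LD-induced
dependence between variants.  TF pairs are screened with the four-term
model adding both main effects and an interaction `β3 · TF1·TF2`; the Wald
test is on `β3`.  The analysis set for every test is the occupied variants
plus the variants occupied by *none* of the investigated TFs (a shared
clean control group).  TFs/pairs surviving Bonferroni correction (within
the single-TF and pair families separately) are "susceptible"; each variant
they occupy is scored with the largest qualifying coefficient (`β1` for
single TFs, `β3` for pairs, positive coefficients only by default) and the
top-K variants form the prioritized set.

The random-intercept model is fit by profiled restricted maximum
likelihood: for a single random intercept the marginal covariance
`σ_e²(I + λ ZZ')` with `λ = σ_b²/σ_e²` has a closed-form block inverse, so
the GLS estimate and the REML log-likelihood reduce to per-block group
sums and the fit is a 1-D bounded search over `log λ` (tolerance 1e-8 on
the log-likelihood, with an explicit boundary check at `λ = 0`, where the
estimate reduces exactly to OLS).  One fit is O(n), which matters because
the null-calibration study refits the model thousands of times.  The test
suite cross-checks coefficients, standard errors and variance components
against statsmodels' `MixedLM`.

### Stage 2 — expression models

Traits (normalized gene expression, or intron-usage splicing ratios — the
machinery is identical) are residualized on covariates (genotype PCs, age,
expression surrogate factors) by OLS projection, then each trait is
regressed on standardized effect-allele dosages of the prioritized variants
within ±1 Mb of the trait span, with an elastic net at mixing parameter
0.5 (the established TWAS convention; the penalty strength is chosen by
nested cross-validation inside each training fold).  Model quality is the
squared Pearson correlation between pooled out-of-fold predictions and the
observed trait over 10 deterministic folds; models with CV R² > 0.01
(strict) are retained.

Two numerical choices deserve note:

* **Fold assignment** hashes `(seed, sample id)`, so folds — and hence
  CV R² and the trained weights — are byte-reproducible and invariant to
  the order samples arrive in.
* **Negative-correlation floor.**  Pooled out-of-fold predictions of a
  null model are *anticorrelated* with the trait (each fold's intercept is
  its training-fold mean, which excludes the held-out samples).  Squaring
  that artifact would pass the majority of pure-noise traits through the
  R² filter, so a negative prediction–observation correlation counts as
  R² = 0.  The `1 − SSE/SST` flavor (which can be negative) is available
  via `r2_mode="sse"`.

### Stage 3 — association from summary statistics

Per gene, the association Z-score combines the model weights `w_lg` with
GWAS single-variant z-scores:

    Z_g = Σ_l  w_lg (σ̂_l / σ̂_g) (β̂_l / se(β̂_l)),   σ̂_g² = wᵀ Γ w

with `σ̂_l` the reference-panel dosage standard deviation and `Γ` the
variant covariance estimated on the training panel (configurable).  Model
variants absent from the harmonized GWAS are dropped and `σ̂_g` recomputed
on the remainder; the retained weight fraction is reported per gene.
Two-sided normal p-values are Bonferroni-corrected over the traits actually
tested.  GWAS harmonization matches variants by `(chrom, pos, sorted allele
pair)`, flips the effect sign when the effect allele equals the panel
reference allele, and drops strand-ambiguous A/T and C/G variants by
default (strand cannot be verified from summary statistics alone).

Enrichment of hits in a disease-gene database uses the hypergeometric
upper tail **strictly beyond** the observed count, `P(X > q)` — the
convention used throughout this pipeline (equivalent to R's
`phyper(q, m, n, k, lower.tail = FALSE)`), against a protein-coding
universe of N = 19,291 by default.  The textbook inclusive tail
`P(X ≥ q)` is available behind the `inclusive` flag; the two differ by the
point mass at `q`.

## Simulation framework

Genotypes are drawn per LD block from a latent Gaussian copula with
exchangeable within-block correlation ρ (two independent haplotypes
thresholded at the target allele-frequency quantile).  Exchangeable rather
than AR(1) correlation keeps LD expectations analytic; none of the
machinery depends on that choice.  Synthetic variants are spaced 25 kb
apart so a ±1 Mb cis window holds ~80 of them rather than the whole panel.

All simulated quantities follow the additive architecture
`f(X) = Σ β_i x_i` with effects drawn from N(0, 1), and noise solved from
the realized genetic variance via `σ_e² = σ_g²(1 − h²)/h²`, so heritability
equals its target in expectation (`h² = 1` gives a noiseless trait; `h² = 0`
drops the genetic component entirely).  Scenarios:

* **causality** — expression `z = f(X) + ε` at `h²_expr`; trait
  `y = z + ε` at `h²_trait`;
* **pleiotropy** — trait effects are redrawn independently on the same
  causal variants, and the trait's noise is rescaled by the *expression*
  heritability (the scenario's defining rule; the redrawn-vs-shared effect
  choice sits behind a flag).

**Null calibration.**  Each batch draws a Bernoulli(½) phenotype
independent of genotype, computes a per-variant GWAS (vectorized logistic
score test by default — exact logistic-model inference with the same null
distribution as the Wald test; a linear fallback exists), then draws random
TF-occupancy assignments (20% of variants) until the mixed-model slope has
two-sided P < 0.05 — prioritization on pure noise.  Expression for the
batch's genes is genuinely heritable in the reference panel (h² = 0.3, 5
causal variants inside the prioritized cis set), so models pass the R²
filter at a realistic rate while remaining unrelated to the phenotype.
Batches run until 2,000 retained gene-replicates have produced TWAS
p-values.  Default panels: 300 reference / 1,000 cohort samples, 4,000
variants in 50 blocks, ρ = 0.3.

**Power study.**  Each replicate simulates fresh genotypes over 200 local
candidate variants (500 reference / 2,000 cohort samples), one gene and one
phenotype, and evaluates three variant-selection protocols on identical
data: `stf` (the causal variants plus an equal number of decoys,
emulating a prioritized set), `all_cis` (all 200 candidates), and
`random_matched` (a uniform draw of the same size as `stf`).  Success is a
TWAS p-value below `0.05 / reps` (the replicate batch plays the role of the
tested transcriptome).  Because protocols share data within a replicate,
protocol contrasts use a paired one-sided exact sign test on discordant
replicates.  Desk-scale defaults are 300 replicates per cell (200 in the
trend sweeps), scaled down from a full production run of 1,000; grid
heritabilities for the monotonicity sweeps (`h²_expr ∈ {0.05, 0.1, 0.3}`
at `h²_trait = 0.1`; `h²_trait ∈ {0.01, 0.03, 0.1}` at `h²_expr = 0.3`;
`n_causal ∈ {10, 20, 40}` at (0.3, 0.03)) were chosen by an analytic power
calculation (`z² ≈ n · h²_expr · h²_trait · q`, with `q` the squared
correlation between predicted expression and the true genetic value) so
that power sits away from the 0/1 boundaries at these sample sizes.

**What the generator does not emulate.**  No recombination maps, no
realistic haplotype or MAF spectra, no population structure, no strand
errors (synthetic alleles are deliberately non-palindromic so harmonization
keeps every variant), and covariates enter expression linearly.  Passing
tests therefore demonstrate correctness of the statistical machinery and
its calibration under the stated generative model, not performance on real
cohort data.

## Data handling details

* QC: variants with missingness > 10%, MAF < 1% or Hardy–Weinberg exact
  test p < 1e-6 are removed.  The HWE test is the standard exact
  (conditional on allele counts) test, computed by the usual recurrence;
  the suite verifies it against a direct multinomial evaluation.
* Missing dosages surviving QC are mean-imputed per variant before model
  training.
* Multiallelic VCF records are skipped with a warning; peak and LD-block
  intervals follow BED half-open 0-based coordinates (interval `[s, e)`
  covers 1-based positions `s+1 … e`); variants outside every LD block get
  singleton blocks.
* Degenerate cases are reported, not raised, wherever a run should
  continue: genes with no prioritized cis-variants or zero trait variance
  are skipped with a reason; genes whose predicted-expression variance is
  zero yield an NA association with a reason; an empty prioritized set
  warns and does not silently fall back to all variants.

## Known limitations

* Only GT-field VCFs (dosage-field inputs and genotype imputation are out
  of scope), and no liftover between assemblies.
* TF interactions beyond pairs are not modeled; pair screening defaults to
  pairs of Bonferroni-significant single TFs to bound the quadratic cost.
* Single-TF and pair coefficients are ranked on a common raw-coefficient
  scale when compiling top-K sets; ranking them in separate interleaved
  families would be an alternative.
* The reference covariance `Γ` comes from the training panel; with an
  external GWAS whose LD differs materially, Z-scores inherit that
  mismatch (as all summary-statistics TWAS methods do).
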