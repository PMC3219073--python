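# Methods

This note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic-data tests do and do not
establish about real exon-array data.

## Probe-level preprocessing

**Background correction** uses the normal+exponential convolution model:
an observed linear-scale intensity is the sum of an exponentially
distributed signal (rate α) and a normal background (μ, σ).  Parameters
are estimated per sample — μ as the mode of a kernel density of the
intensities (Silverman bandwidth on a robust scale, `min(sd, IQR/1.34)`,
so a bright-signal tail cannot oversmooth the background mode), σ from the
mean squared deviation below the mode, α from the mean excess above it —
and each probe is replaced by the posterior mean of its signal,
`E[S|O] = a + σ·φ(a/σ)/Φ(a/σ)` with `a = O − μ − σ²α`.  The output is
strictly positive and monotone in the input.  A sample with constant
intensities is rejected.  Correction is optional (`--no-bgcorrect`)
because synthetic data are generated directly on the log2 scale without an
additive background component (set `background_scale > 0` to add one).

**Quantile normalization** maps every sample onto the across-sample mean
of order statistics.  Ties within a sample share the mean of their target
quantiles; a single-row matrix collapses to the row mean.  After
normalization, every column's sorted values agree with the reference to
1e-9.

## Gene model and FIRMA scores

Each gene's log2 submatrix is fitted with `log2 I_ks = c_s + p_k + r_ks`
by Tukey median polish: rows (probes) swept first, then columns, the
overall level carried by the chip effects `c_s` and the probe effects
median-centered; iteration stops when the largest adjustment falls below
`tol = 1e-6` or after `max_iter = 10` sweeps (standard probe-model
practice; the reconstruction identity `c + p + r = data` holds exactly at
any iteration count).  The model deliberately contains no exon term — the
splicing signal of interest must surface in the residuals.

The FIRMA score of probe set *j* in sample *s* is the median residual of
its probes divided by the gene's robust residual scale
`s_g = 1.4826 · median|r|`, floored at 1e-6 to avoid division blow-ups
(a gene with all-zero residuals then scores 0, with a logged warning).
Scores live on the log2-residual scale — residuals of log2 intensities
already are log2 fold-deviations, so no further transform is applied (a
literal log of signed scores would be undefined).  Genes with a single
probe set still receive scores (their residual structure reflects
probe-level noise) and are flagged in the results; nothing in the method
requires their exclusion.

Gene-level expression is the chip-effect vector of the same polish,
i.e. RMA-style summarization on background-corrected, quantile-normalized
data.

## TIN profiles and subtypes

Deviating exon usage is counted against the lower/upper 1st percentiles of
**all** scores in the series, computed with the linear-interpolation
percentile definition (the common statistical default; the thresholds used
are always logged and reported so another percentile dialect would be
visible).  Comparisons are strict (`<` lower, `>` upper): ties at the
threshold are not flagged.  On continuous scores this flags 2% of all
(exon, sample) pairs, the property the conservation test checks.

Relative amounts use the arithmetic mean of per-sample counts as the
cohort reference (`rel_x = log2(n_x / mean(n_x))`; a geometric-mean option
exists).  A zero count makes the log-ratio undefined; the recommended
pseudocount is 0.5.  Subtype calls are strict comparisons against fixed
constants — sTIN when `|rel_skip − rel_incl| > 0.7`, oTIN when
`|rel_total| > 1.0` — and the two flags are independent, so a sample may
carry both.  Thresholds for *scores* are computed within each series
(test and validation series are processed independently), while the
subtype cut-offs are fixed constants shared across series.

Because skew is measured **relative to the cohort**, a subset of samples
with strongly skewed deviations shifts the reference and gives the
remaining samples an opposite-sign skew.  This is inherent to the relative
measure, not an artifact of the implementation; recovery claims for sTIN
therefore concern the samples with injected skew (which are called sTIN
with the correct, positive-skipping sign), not sTIN specificity in the
remainder.

**Paired tumor–normal comparison.**  Scores are computed jointly on
tumors and normals, relative amounts over the joint cohort, and each
tumor's `rel_total` is differenced against its paired normal; the
differences are summarized by a paired t test.  This joint-scoring
reconstruction of the paired normalization is a design choice of this
package; the exact historical procedure it replaces is not published in
reusable form.  Identical pairs (zero variance) are reported as a
"no variation" outcome rather than an undefined statistic.

## Splicing-factor association

Per-gene Pearson correlation of log2 expression with `rel_total`,
two-sided p from the t distribution with n−2 df; significance is raw
p < 0.05 with **no** multiple-testing correction (that is how the
correlation counts are defined; an FDR option exists but defaults off).
Constant genes are excluded with a logged count.

*Random-set null:* sets of equal size sampled without replacement from all
genes on the platform, splicing factors included (exclusion available).
Each set contributes its significant-gene count, mean significant r, and
negative:positive ratio; the comparison p is the fraction of sets at least
as extreme, reported as `< 1/n_sets` when none are.  *Permutation null:*
the `rel_total` vector is shuffled across samples; each permutation
contributes the median r over the gene set and the significant
negative/positive counts.  The empirical p for the observed median r is
one-sided on |median r| with the add-one rule
`(1 + #{|median r_perm| ≥ |obs|}) / (n_perm + 1)`; the negative-excess
comparison is reported as the plain fraction of permutations with
`n_neg − n_pos` at least the observed.  Both procedures are
bit-reproducible given the seed.

*Clustering:* samples are clustered on per-gene median-centered
splicing-factor expression (`--no-center` disables), Euclidean distance,
complete linkage, samples pre-sorted lexicographically so tie-breaking is
deterministic; the dendrogram is cut at the root into two groups, and the
quantitative stand-in for reading groups off a dendrogram is Fisher's
exact test of cluster membership against deviation-amount direction
(`rel_total` above/below the cohort average), optionally restricted to
oTIN samples.

## Survival analysis

Kaplan-Meier estimation and the log-rank (Mantel-Cox) test are delegated
to lifelines; survival at *t* is read off the right-continuous step
function, with events preceding censorings at tied times.  Cox
proportional-hazards regression is implemented in-package: Newton
iterations on the partial likelihood to `|Δβ| < 1e-8` with step-halving,
Efron's tie correction by default (Breslow via `ties="breslow"`), Wald
95% CIs `exp(β ± 1.96·SE)`.  Efron is the default because it is the
better approximation with the modest tie counts expected at yearly-scale
follow-up.  Perfect separation (monotone likelihood) and collinear or
constant covariates raise explicit errors naming the covariate.
Categorical covariates are dummy-coded against declared reference levels:
stage II, microsatellite-stable, female, right colon.

Grouping schemes: `sTIN`, `oTIN`, `either` (union) and `both`
(intersection), always the positive class versus the rest; degenerate
splits (no positives or no negatives) are an error.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with one seeded random stream so identical configs and seeds give
byte-identical output files.

* **Intensities:** `log2 I = c[g,s] + p[k] + δ·Z[j,s] + ε`, with
  `c ~ N(8, 1.5²)`, probe affinities `p ~ N(0, 0.5²)` centered per gene,
  noise `ε ~ N(0, σ²)`, σ = 0.25.  Deviations are injected coherently at
  the probe-set level (`Z ∈ {−1, 0, +1}` applied to all probes of the
  set), matching what the score is designed to detect; incoherent
  per-probe disturbance is covered by ε.
* **Deviation rates:** baseline 0.015 per (probe set, sample);
  TIN-positive samples (10% of the cohort) inject at 3× that rate with
  4:1 skip:inclusion sign odds, baseline samples at 1:1.  These rates put
  baseline samples near the 2% flagged average and TIN samples at ~4.5% of
  probe sets deviating — inside the per-sample range reported for real
  exon-array cohorts — while keeping the 3×-rate contrast that the
  recovery tests quantify.  The skew ratio applies to the TIN subset
  because skew is a relative measure: a cohort-wide sign bias would cancel
  in the cohort reference and produce no skewed samples at all.
* **Effect size** δ = 1.5 log2 units, the condition at which detection
  power is assessed (AUC > 0.9 in the acceptance suite; in practice ≈ 1.0
  at δ/σ = 6).
* **Splicing factors:** the first `n_sf_genes` genes' expression is
  `a_g − β·burden_std[s] + N(0, σ_sf²)` with β = 1 and σ_sf = 0.3, where
  `burden_std` is the standardized injected-deviation count per sample.
  This coupling is deliberately strong (per-gene |r| ≈ 0.9) so that
  recovery tests have sharp expectations; real cohorts show the same
  *pattern* (majority-negative significant correlations) at weaker
  per-gene correlations.  `generate_sf_expression` also provides
  standalone SF + matched-null gene matrices for module-level tests.
* **Clinical data:** exponential event times with hazard
  `h0·exp(log HR · TIN+)`, h0 = 0.05/year, true HR = 3, administrative
  censoring at 10 years (`censor_time` must be positive; the
  everyone-censored limit is exercised at 1e-6 years).  Covariates are
  drawn independently of outcome: stage II/III 55/45, MSI 20%, age
  N(70, 10²) clipped to 30–95, sex 50/50, location right/left/rectum
  40/30/30.

Defaults are desk-scale: 300 genes × 4–12 probe sets × 4 probes ×
80 samples (≈ 10⁶ intensity values, seconds to simulate and score).
Replicate-series studies in the tests and acceptance script use 650 genes
× 40 samples per series, a size at which per-sample deviation counts
(~190 for TIN samples) give the count-based oTIN call adequate Poisson
resolution; at much smaller series the 2×-mean oTIN cut-off is
noise-limited rather than method-limited.

### What the synthetic tests do and do not show

The generator matches the analysis assumptions by construction: additive
probe structure, coherent exon-level deviations, monotone SF coupling,
proportional hazards.  Passing tests therefore demonstrate that the
implementation recovers what the model class can express — they do not
demonstrate robustness to probe sequence effects, cross-hybridization,
batch effects, mutually exclusive exons, or non-proportional hazards, none
of which are simulated.  Two further divergences from real cohorts are
worth naming: simulated TIN-positive samples are high-burden only, so
low-side oTIN (below-average deviation amounts, which real series do show)
arises only from sampling noise and the oTIN-restricted two-group
clustering is degenerate on synthetic data (the acceptance script
therefore reports cluster agreement over all samples); and the single
TIN-positive subset couples the oTIN and sTIN phenotypes, which in real
series overlap only partially.

Processing a real series end to end — CEL files preprocessed externally
into the probe-intensity TSV, the core chip definition as the 3-column
TSV, and a curated splicing-factor list — is the intended real-data entry
point and runs through exactly the same commands; headline statistics of
published cohorts are expected to be reproduced only at that full scale,
not at desk scale.

## Numerical conventions and degenerate inputs

* Percentiles: linear interpolation between order statistics.
* Strict inequalities at all thresholds (score flags, subtype cut-offs).
* Median polish: row sweep first; convergence on maximum absolute
  adjustment; reconstruction identity exact to floating point.
* FIRMA scale floor 1e-6; single-probe-set genes flagged, not dropped.
* Correlations: r clipped to [−1, 1]; |r| = 1 assigned p = 0; constant
  genes excluded, never silently.
* Clustering: lexicographic sample order before linkage for deterministic
  tie-breaking.
* Cox: covariates centered before iteration (shifts cancel in the partial
  likelihood); step-halving; separation declared when the likelihood is
  monotone (|β| diverging), naming the covariate.
* Readers reject identifier mismatches across files; `allow_subset`
  intersects with a logged count.  Writers emit fixed column orders;
  write→read round-trips are exact for identifiers and lossless for reals
  (round-trip float parsing).
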