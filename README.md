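# tinstab — transcriptome instability analysis for exon arrays

`tinstab` quantifies **transcriptome instability (TIN)**: genome-wide
disruption of pre-mRNA splicing in tumor samples, measured from exon
microarray data as the per-sample amount of *deviating exon usage*.  It is
aimed at cancer transcriptomics groups working with Affymetrix exon-array
style data (probe → probe set/exon → transcript cluster/gene), and at
anyone who wants a tested, scriptable re-implementation of the FIRMA-based
TIN workflow: splicing scores, instability subtyping, splicing-factor
association, and survival stratification — together with a synthetic-data
generator that provides ground truth for every stage.

## The method

**Probe model and FIRMA scores.** After optional normal+exponential
background correction and inter-chip quantile normalization, the log2
intensities of each gene *g* are fitted with the additive probe-level model

    log2 I_ks = c_s + p_k + r_ks

by Tukey median polish (no exon term: a deviating exon must remain visible
in the residuals).  `c_s` is the gene-level expression of sample *s*,
`p_k` the probe affinity.  The FIRMA score of exon (probe set) *j* in
sample *s* is the robustly standardized median residual

    F_js = median_{k in j}(r_ks) / (1.4826 * median|r_g|)

Strongly negative scores indicate candidate exon skipping, strongly
positive scores candidate inclusion.

**TIN profiles.** Scores beyond the lower/upper 1st percentiles of all
scores in the series count as deviating exon usage.  Per-sample counts are
expressed relative to the cohort average, `rel_x = log2(n_x / mean(n_x))`,
and two subtypes are called with fixed cut-offs:

* **sTIN** (skewed): `|rel_skip − rel_incl| > 0.7` — preferential skipping
  or inclusion;
* **oTIN** (overall): `|rel_total| > 1.0` — unusually high or low total
  amount of deviating exon usage.

**Splicing-factor association.** Gene-level expression of a splicing-factor
gene set is correlated (Pearson) with `rel_total` per sample, benchmarked
against random gene sets of equal size and against permutations of the
`rel_total` vector; samples are hierarchically clustered (Euclidean,
complete linkage) on splicing-factor expression.

**Survival.** Patients grouped by TIN status are compared by Kaplan-Meier
estimation, the log-rank test, and Cox proportional-hazards regression
(Newton on the partial likelihood, Efron or Breslow ties), univariate or
adjusted for stage, MSI, age, sex and tumor location.

## Worked example

```python
import tinstab as ts

ds = ts.simulate_dataset(seed=1)                     # synthetic cohort
firma = ts.FirmaModel(ds.intensities, ds.chipdef,
                      background_correction=False).fit()
tin = ts.TinModel(firma.scores).fit(pseudocount=0.5)
print(tin.summary())
```

```
TIN profiles
  samples          : 80
  score thresholds : lower -4.1179, upper 1.6324
  mean deviating exons/sample: 48.7 (range 29 to 119)
  sTIN (|skew| > 0.7) : 30
  oTIN (|rel_total| > 1.0): 8
  both subtypes    : 8
```

The thresholds are the 1st/99th percentiles of all 2,434 × 80 FIRMA scores,
so 2% of all (exon, sample) pairs are flagged; the 8 oTIN calls are exactly
the 8 simulated TIN-positive samples.  Downstream:

```python
sf = ts.SplicingFactorModel(firma.expression, tin.rel_total, ds.sf_genes).fit(seed=1)
print(sf.correlations.summary())
table = ts.build_survival_groups(tin.profiles, ds.clinical, "oTIN")
print(ts.cox_ph(table, ["group"]).summary())
```

```
correlation of 40 genes with deviating exon usage (alpha 0.05)
  significant: 40 (100.0%)
  negative / positive among significant: 40 / 0
  mean r among significant: -0.881
...
Cox proportional hazards (efron ties): 80 patients, 33 events, log partial likelihood -135.473
covariate               HR            95% CI         p
group                 2.29    0.94 to 5.57      0.06762
```

All 40 simulated splicing factors correlate negatively with deviation
burden (the generator couples them with β = 1), and oTIN-positive patients
show an elevated hazard (the generator's true HR is 3; at 8 positives of
80 the estimate is noisy, as the confidence interval shows).

The same pipeline is available from the shell:

```sh
tinstab --seed 1 simulate --out-dir run/
tinstab firma --chipdef run/chipdef.tsv --intensities run/intensities.tsv \
        --out-scores run/scores.tsv --out-expression run/expr.tsv --no-bgcorrect
tinstab tin --scores run/scores.tsv --out-profiles run/profiles.tsv --pseudocount 0.5
tinstab --seed 1 run-all --out-dir run/       # everything, plus report.txt
```

Real data enter through the same files: a 3-column chip-definition TSV
(`probe_id  probe_set_id  gene_id`), a probe-intensity TSV, a
splicing-factor gene list (one identifier per line), and a clinical CSV
(`sample_id,time_years,event,stage,msi,age,sex,location`).

## Layout

- `src/tinstab/io.py` — file formats and validation
- `src/tinstab/preprocess.py` — background correction, quantile normalization
- `src/tinstab/firma.py` — median polish, FIRMA scores, gene expression
- `src/tinstab/tin.py` — thresholds, counts, subtype calls, paired comparison
- `src/tinstab/sf.py` — splicing-factor association, nulls, clustering
- `src/tinstab/survival.py` — Kaplan-Meier, log-rank, Cox PH
- `src/tinstab/simulate.py` — synthetic cohorts with ground truth
- `src/tinstab/cli.py` — `tinstab` command-line interface
- `docs/methods.md` — model details, parameter choices, limitations
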