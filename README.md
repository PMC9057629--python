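# tilprog

Prognostic stratification of bulk tumor cohorts from multiplexed single-cell
T-cell profiles.

Tumor-infiltrating T cells are heterogeneous: some subsets (e.g.
*GZMK*⁺KLRG1⁺ effector-memory cytotoxic cells, Helios⁺ regulatory T cells)
track with good outcomes, others (CD38⁺ peripherally derived Tregs,
dysfunctional CD103⁺ cytotoxic cells) with poor ones. `tilprog` implements
the computational chain that connects a hashed CITE-Seq/TCR-Seq experiment to
survival differences in bulk RNA-Seq cohorts:

1. **Hashtag demultiplexing** — per-barcode HTO counts are rescaled to a
   fixed total (100); identity goes to the argmax tag, with thresholds for
   `negative` (weak top tag / few raw UMIs) and `doublet` (strong second
   tag, or a top-value tie).
2. **ADT profiles and cluster linkage** — antibody-derived-tag counts are
   depth-scaled, CLR-transformed within each cell, and standardized;
   stimulated clusters are linked to their cognate nonstimulated clusters by
   Pearson correlation of mean ADT profiles (or by gene-set enrichment of
   marker sets on mean expression rankings).
3. **Signature derivation** — one-vs-rest Wilcoxon rank-sum cluster markers
   (strict `min.diff.pct` filter, biotype/prefix exclusions, p-then-effect
   ordering) and correlation signatures (top genes co-varying with a
   reference such as *TCF7*, *HAVCR2*, *FGFBP2*); cells are scored by mean
   signature expression.
4. **TCR clonality** — clonotypes keyed on TRB CDR3 nucleotide sequence
   within patient; per-cell clone frequencies relative to the patient ×
   tissue group; per-cluster expansion-bin composition; inter-cluster
   clonotype sharing with a within-patient permutation test.
5. **Per-patient preranked GSEA** — genes standardized across patients
   (z = (x − μ_g)/σ_g), each patient's genes ranked by their own z, and each
   gene set scored by the weighted Kolmogorov–Smirnov enrichment score

   ES = extremum of the running sum with hit steps |z|^p / Σ_hits |z|^p and
   miss steps −1/(N − N_hits),

   against a gene-sampling permutation null; NES = ES / mean |null ES| of the
   same sign; Benjamini–Hochberg adjustment across patients per gene set.
   Patients are **Enriched** (NES > 0, BH-adjusted p < 0.05), **Depleted**
   (NES < 0, BH-adjusted p < 0.05), or neither.
6. **Survival comparison** — Kaplan–Meier curves and the two-group log-rank
   test between enriched and depleted patients, optionally restricted to a
   stage subset (e.g. Stage II–III); stage-composition summaries and overlap
   between classifications.

A synthetic-data module generates both data layers — hashed droplet runs
(HTO/ADT/RNA/TCR with singlet–doublet–ambient structure, cluster markers,
skewed clonal expansion) and bulk cohorts (planted signature shift,
class-dependent exponential survival) — with complete ground truth, so every
stage is testable without external downloads.

## Worked example

```python
import tilprog as tp

cfg = tp.CohortSimConfig(n_patients=200, effect_size=1.5, seed=42)
cohort, signature, truth = tp.simulate_bulk_cohort(cfg)

params = tp.EnrichmentParams(n_perm=2000, seed=0, alpha=0.05)
results = tp.enrich_cohort(cohort, {"T_sig": signature.genes}, params)
classes = tp.classify_patients(results, params).set_index("patient")["label"]
print(classes.value_counts().to_dict())

res = tp.stratified_survival(cohort.clinical, classes)
print(f"log-rank chi2 = {res.test.chisq:.2f}, p = {res.test.p:.2e}")
res23 = tp.stratified_survival(cohort.clinical, classes, ["II", "III"])
print(f"stage II-III: chi2 = {res23.test.chisq:.2f}, p = {res23.test.p:.2e}")
```

prints

```
{'neither': 120, 'enriched': 40, 'depleted': 40}
log-rank chi2 = 13.72, p = 2.12e-04
stage II-III: chi2 = 6.03, p = 1.40e-02
```

The simulated cohort plants a ±1.5 z-unit signature shift in 20% enriched and
20% depleted patients and a 3× hazard for the depleted class. The classifier
recovers exactly the planted 40/40 split, and the enriched-vs-depleted
log-rank test rejects strongly, both over all stages and within the Stage
II–III subset.

The same steps are available from the shell:

```sh
tilprog simulate cohort --seed 4 --out cohort1
tilprog enrich --expr cohort1/expression.csv --gmt cohort1/signatures.gmt \
        --out enrich.csv --n-perm 2000 --seed 5
tilprog survive logrank --clinical cohort1/clinical.csv --classes enrich.csv \
        --stages II,III
```

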