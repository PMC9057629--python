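# Methods

This note documents the models, conventions and parameter choices behind
`tilprog`, in the order the pipeline runs.

## Hashtag demultiplexing

Each barcode's hashtag (HTO) counts are rescaled so they sum to a fixed
total (default 100). Identity is the argmax tag; an
argmax-else-negative/doublet rule by itself fixes no numeric thresholds, so
the thresholds that make it operational are explicit parameters with
defaults on the 0–100 scale:

* `singlet_min = 60` — a top tag below this is `negative`;
* `doublet_second_min = 30` — a second tag at or above this is `doublet`
  (an exact tie at the top is also a doublet: a tie is evidence of two
  samples);
* `min_total_raw = 10` — barcodes with fewer raw hashtag UMIs are `negative`
  regardless of composition.

Labels are scale-invariant (multiplying a barcode's raw counts by any
positive constant changes nothing) and every barcode receives exactly one
label.

## ADT normalization and cluster linkage

Antibody-derived-tag counts are (1) depth-scaled — each cell rescaled so its
panel total equals the mean per-cell total, (2) CLR-transformed within the
cell, `v_i → ln((v_i + 1) / geomean_j(v_j + 1))` (the +1 pseudocount makes
zeros well defined; the CLR margin is within-cell, reading the panel as a
composition), and (3) standardized per antibody across cells. CLR output
sums to zero per cell before standardization (log-ratio closure).

Cluster profiles are arithmetic means of normalized values. Stimulated and
nonstimulated clusters are linked by Pearson correlation of profiles over a
shared antibody subset (≥ 3 channels; the panel subset is a config list so
isotype-control-like channels can be excluded), pairing each stimulated
cluster with its row-argmax. An expression route ranks each stimulated
cluster's genes by mean expression and scores each nonstimulated cluster's
marker set with the enrichment engine, pairing by row-argmax NES.

## Signatures

Cluster markers are one-vs-rest two-sided Wilcoxon rank-sum tests per gene
(normal approximation with tie correction; exact enumeration when both
groups have ≤ 8 cells). A gene is kept when

* (fraction expressing inside − fraction expressing outside) > `min_diff_pct`
  (strict, default 0.25);
* its rank-based direction is positive (AUC = U/(n₁n₂) > 0.5). The
  direction filter is deliberately rank-based rather than the sign of the
  mean difference: selection is then exactly invariant under per-gene
  rank-preserving transforms, which is the defining property of a rank-sum
  selection. The mean-difference effect (or log-fold-change, behind a flag)
  is still reported and used for ordering;
* its name does not carry an excluded prefix (default `AP-`) and its
  biotype (when annotated) is not excluded (default lincRNA, miRNA).

Survivors are ordered by ascending p, then descending effect, then gene id,
and truncated to `top_n` (default 100).

Correlation signatures take the top k (20–30) genes by Pearson correlation
with a reference gene across a chosen cell subset, reference first, ties
broken by gene id. The candidate universe defaults to a supplied
variable-gene list when given, otherwise all genes.

Scoring and correlation operate on log1p of depth-scaled counts (per-cell
total rescaled to the cohort median). This convention is fixed here because
normalization upstream of signature work is out of scope; any monotone
per-gene reparameterization leaves marker membership unchanged (see above).
Cell scores are arithmetic means over the signature genes present (missing
genes are counted and reported); scores are linear in the expression values.

## TCR clonality

Clonotypes are keyed on the TRB CDR3 nucleotide sequence *within* patient —
the same sequence in two patients is two clones; cells without a productive
TRB are unassigned (`NA`). Paired-chain keying is available behind a flag.
Per-cell clone frequency is clone size over the patient × tissue group size
(tumor-infiltrating cells and normal-tissue cells form separate
denominators); unassigned cells join neither numerator nor denominator, so
Σ_cells 1/clone_size equals the number of distinct clones per group.
Clonal composition bins default to sizes {1}, {2–5}, {≥6}; the bins are
parameters because no canonical bin set exists.

Sharing between two clusters counts distinct clonotypes present in both.
Significance comes from permuting cluster labels among the two clusters'
assigned cells within each patient (preserving cluster sizes and patient
composition), with the add-one estimator p = (1 + #{null ≥ obs})/(1 + n_perm).
The permutation design is this package's own choice of test; no agreement
with any externally reported sharing p-value is claimed.

## Per-patient preranked enrichment

Genes are standardized across patients, z_gp = (x_gp − mean_g)/sd_g (sample
sd; zero-variance genes dropped), and each patient's genes are ranked by
their own z, descending, ties broken by gene id. A cohort-averaged z would
be identical for every patient and could not produce per-patient classes;
the per-patient form is the one used throughout.

The enrichment score is the signed extremum of the weighted KS running sum
(hit steps |z|^p_w normalized over hits, default p_w = 1; miss steps
−1/(N − N_hits)). With p_w = 0 this is the classic unweighted KS statistic,
verified exhaustively against a brute-force oracle for all rankings of
N ≤ 8 and all set placements, and the weighted form is cross-checked against
the R `fgsea` reference implementation.

Because per-patient ranked lists admit no phenotype permutation, the null is
gene-sampling: ES of random same-size gene sets from the universe, drawn
once per (patient, set size) and shared across sets of that size.
p = (1 + #{same-sign null ≥ |ES|})/(1 + #same-sign null);
NES = ES / mean |same-sign null ES|. A set spanning the whole universe (no
misses) or a sign with no null draws is flagged degenerate (p = 1, NES = 0).
Under a null cohort this construction is calibrated: pooled p-values are
uniform to KS distance < 0.01 at n_perm = 2000.

BH adjustment is step-up with monotonicity enforcement (statsmodels
`fdr_bh`), applied by default across patients for a fixed gene set
("patients_per_set"), which matches classifying a cohort per gene set; the
per-patient family ("sets_per_patient") is available as an alternative.
Classes: enriched iff NES > 0 and padj < α (default 0.05);
depleted iff NES < 0 and padj < α; otherwise neither.

## Survival

Kaplan–Meier curves and the two-group log-rank test (O − E with
hypergeometric variance, χ² with df = 1) are computed with lifelines; both
are verified against hand oracles — KM equals the empirical survival
function exactly without censoring, and the log-rank statistic matches the
O−E formula and orders the exact permutation distribution consistently at
small n. Events precede censorings at tied times (standard convention).
"Neither" patients are excluded from enriched-vs-depleted comparisons; a
three-group run is possible by relabeling. Stage strings are parsed
AJCC-style ("Stage IIA" → II); stage-restricted comparisons (e.g. II–III)
drop patients outside the subset and flag, rather than test, when a class
empties. Classification overlap reports |A∩B| / |A| rounded to integer
percent over the enriched sets of two classifications on the same patients.

## Synthetic data: what it emulates, and what it does not

No distributional description of the real assays is available, so all
generator choices are stand-ins chosen once for plausibility:

* **Counts** are Poisson-gamma (negative binomial) with shared shape
  `dispersion = 2` — typical over-dispersion for droplet UMI data, and
  sufficient for the rank-based downstream stages.
* **HTO**: singlets put 1 − `ambient_fraction` (default 0.95) of hashtag
  counts on the own tag, the rest uniformly on other tags; doublets are the
  sum of two independently drawn singlet profiles (droplet
  co-encapsulation). Per-cell hashtag *totals* use their own NB shape
  (`hto_total_shape = 10`, CV ≈ 0.32): with the count-level shape the two
  members of a doublet would often differ in depth by far more than any
  threshold method can detect, contradicting the separable regime the
  recovery checks assume. Defaults: 8 tags (patient/tissue pairs), 8%
  doublets, depth 200.
* **RNA**: 5 clusters, 20 disjoint marker genes each, elevated 4-fold on a
  shared lognormal baseline; depth 2000 over 1000 genes.
* **ADT**: 23-antibody panel with lognormal cluster-specific means.
* **TCR**: per-patient clone probabilities are Dirichlet with concentration
  0.3 (small → skewed, expanded clones exist); CDR3 strings are synthetic
  random sequences, unique per patient clone. Defaults: 93% of cells carry
  any chain and 86% of those are paired (e.g. 27,999 paired of 32,550
  assigned cells), representative of 10x TCR enrichment at this scale.
* **Bulk cohort**: per-gene Gaussian log2 expression (mean ~N(8, 2), sd
  ~U(0.5, 1.5)); a 50-gene signature shifted by ±`effect_size` z-units in
  20% enriched / 20% depleted patients. Survival is exponential:
  enriched at `baseline_hazard` = 0.01/month (median ≈ 69 months, a typical
  overall-survival scale), depleted at 3× that, "neither" at the geometric
  mean of the two (the middle class needs *some* hazard and the geometric
  mean keeps it between the extremes), and an
  optional per-stage multiplier (default 1). Censoring: with probability
  `censor_rate` = 0.3 a patient is censored uniformly before their event
  time, so the empirical censoring fraction is exactly binomial. Stages
  I–IV with probabilities (0.15, 0.30, 0.35, 0.20); an MSI-high flag at 15%.

Not emulated: sequencing error, ambient mRNA contamination of the
transcriptome, batch effects, doublet transcriptomes (a doublet's RNA/ADT
are drawn from a single cluster; only its hashtags are mixed), clone-cluster
coupling, and non-proportional hazards. Passing tests therefore demonstrate
correctness of the *computational chain* under a known generative model —
threshold demultiplexing recovers planted tags, rank-sum selection recovers
planted markers, the enrichment classifier is calibrated under the null and
recovers planted classes, the log-rank test detects planted hazard ratios —
not performance on real tissue data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep the whole suite
in minutes on one CPU: 800–2,000 cells per simulated run; 200–300 patients,
1,000 genes and 2,000 permutations per simulated cohort; 500 random gene
sets for null calibration; 10-seed sweeps for recovery and power. All
randomness flows through explicit integer seeds (numpy `SeedSequence`
spawning for independent streams); identical config + seed reproduces every
fixture byte for byte.

Degenerate inputs are handled, not hidden: zero-total barcodes → negative;
zero-variance genes dropped from rankings with a log line; zero-variance
profiles → missing correlations; full-universe gene sets and empty-sign
nulls → flagged results; no-event survival comparisons → flagged p = 1.
Ties break deterministically everywhere (gene id in rankings and signatures,
argmax-first in running sums, top-value ties → doublet).

## Known limitations

* The gene-sampling null treats genes as exchangeable; correlated gene
  modules in real cohorts make it anti-conservative, as for any preranked
  GSEA with gene-set permutation.
* The weight exponent and BH family are conventions, not identities;
  the defaults (p_w = 1, patients-per-set) are declared package choices.
* No agreement with externally reported cohort survival p-values is
  claimed; the summary operations are exercised on count examples at
  realistic scale (86% paired TCR of 32,550 cells; 76% overlap of 33
  enriched patients).
* Which antibodies to drop from a correlation panel (e.g. isotype-control
  channels) is dataset-specific; the panel subset is a parameter.
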