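# Methods

This note documents the models and procedures implemented in
`budphase`, the assumptions behind them, the synthetic data they are
validated on, and the numerical choices that were genuinely open.

## The analysis chain

### Expression preprocessing

Counts are converted to transcripts per million,
`TPM_ij = (c_ij / L_i) / Σ_g (c_gj / L_g) × 10⁶`, so each sample column
sums to 10⁶ and within-sample length bias is removed. Three sequential
filters follow, each gene being charged to the first rule it fails:
mean raw count < 3 (lowly expressed), zero counts in more than 75 % of
samples (mostly absent), and coefficient of variation (sd/mean) < 0.3
(flat). Boundary semantics are inclusive for survival (mean ≥ 3,
zero-fraction ≤ 0.75, CV ≥ 0.3). The CV is computed on TPM by default —
TPM is the expression unit of the analysis — with a switch for raw
counts. Missing values are rejected rather than imputed.

The differential-expression caller is deliberately simple: a per-gene
Welch t-test on log₂(TPM+1) between dormant (default: endodormancy +
dormancy release) and non-dormant samples, BH-adjusted, flagged at
padj < 0.05. It is a stand-in behind a pluggable interface — a DEG
table produced by a dedicated count model (e.g. DESeq2 run separately)
can be imported from TSV instead. Two caveats are inherent to any
two-group contrast on a time course and are worth knowing: (i) genes
whose expression peaks near the group boundary have large within-group
variance and little mean difference, so they are systematically
under-called; (ii) the split of a continuous season into "dormant" and
"non-dormant" is a parameter, not a biological fact. For this reason
the synthetic end-to-end run clusters the filter-surviving gene set
rather than the DEG subset (`cluster_on="filtered"`), while the default
`run_pipeline` follows the published workflow (`cluster_on="deg"`).

### Profile clustering

Gene profiles are compared by Pearson-correlation distance
`d(i,j) = 1 − r(i,j)` across the reference cultivar's samples; since
Pearson r is invariant to per-gene affine maps, clustering TPM rows and
z-scored rows yields the same partition (asserted as a test).
Agglomerative clustering (scipy; complete linkage by default — the
conventional default of hclust-style environments; average and Ward
available) is cut to exactly k = 10 groups. Gene z-scores use the
sample standard deviation (n−1); the population convention is a
parameter. Cluster centroids are the mean member z-score per timepoint,
where a timepoint is a calendar date (replicate trees, and cultivars
when several are supplied, are averaged; a cultivar×date axis is a
config option). Clusters are then relabeled 1..k by the chronology of
their expression peak; the ordering uses the reference cultivar's
centroids, because averaging across cultivars smears post-onset peaks
over the dates at which different cultivars reach them. Peak ties are
broken by larger cluster first. Per-gene Pearson correlation with the
own-cluster centroid, computed on the same timepoint axis, quantifies
how well a gene represents its cluster.

### Marker panel

One marker per chosen cluster (default 1, 4, 5, 7, 8, 9, 10; small or
redundant clusters are typically left out, and the set is a parameter):
among genes with mean TPM ≥ 10 and gene-family size ≤ 5 (both
thresholds quantify qualitative criteria — assayability and primer
specificity — and are config keys), the gene with the highest centroid
correlation wins; ties break by higher mean TPM, then lexicographic id,
so the panel is invariant to input order. Primer designability cannot
be decided computationally; a user-supplied exclusion list stands in
for it.

### Enrichment

For a cluster of n genes from a universe of N (by default the analysed
gene set itself, not the genome), a set annotating K universe genes and
k cluster genes scores the exact hypergeometric upper tail P(X ≥ k) —
identical to the one-sided Fisher exact test on the 2×2 table, and the
GO path shares the hypergeometric code. TF-target and motif families
are BH-corrected per cluster × annotation kind (matching per-cluster
reporting; a global family is available). GO terms are filtered at raw
p < 0.005 and the ten smallest-p terms reported. Motif occurrences are
collapsed to gene-level presence/absence before testing. GO annotations
are used flat, without ontology-graph propagation — enrichment of a
term does not imply enrichment of its ancestors here.

### Stage classifier

Marker expression is normalized per cultivar by the replicate-mean of
the October reference sample (the beginning of endodormancy, present
for every cultivar; with two October dates the earliest is used).
Ratios, not log-ratios, are the default (`log2` optional). Both the
RNA-seq training side and the qPCR prediction side are normalized the
same way — projecting ratio-scaled data onto a raw-TPM PCA would mix
scales. Samples × markers are then mean-centered (unscaled) and
projected on the top two right singular vectors; the loading entry of
largest magnitude in each component is made positive, so the
decomposition is deterministic. Data of rank 1 (all samples on a line)
are allowed: the second component is an arbitrary orthonormal
complement with explained fraction 0.

The classifier is a softmax (multinomial logistic) regression on the
2-D scores minimizing the L2-penalized negative log-likelihood
`−Σ log softmax(Wx+b)_y + (λ/2)‖W‖²` (intercepts unpenalized), solved
with L-BFGS-B and an analytic gradient at gradient-norm tolerance 1e-8
from a zero start — the problem is convex, so the fit is deterministic.
λ is chosen from ten log-spaced values in [1e-4, 1e4] by stratified
5-fold cross-validated accuracy; ties resolve toward the stronger
penalty. Prediction is the argmax class probability with ties broken by
chronological stage order. Evaluation repeats stratified train/test
splits (default test fraction 0.3, stratified by stage), refits the
CV-regularized model per split, and reports support-weighted F1. An
independent sklearn fit cross-checks the optimizer in the tests; it is
never the implementation.

### Phenology and qPCR

Dormancy release is the earliest forcing-test observation with bud
burst ≥ 50 % (strict > optional), or the linearly interpolated crossing
date; a never-crossing series returns an explicit "not released" value.
Stage labels follow a per-cultivar calendar: organogenesis (July to
August) and paradormancy (September) windows, endodormancy from its
onset (October) until the release window, dormancy release within ±7
days of the release date (samples labelled "release" are single dates,
so a window is needed; its width is a parameter), ecodormancy from
there to flowering.

RT-qPCR quantification uses the relative standard-curve method: per
gene, OLS of Cq on log₁₀(quantity) over ≥ 3 dilutions (slope must be
negative; efficiency = 10^(−1/slope) − 1), inverted to
quantity = 10^((Cq−intercept)/slope). Technical replicate Cq values are
averaged before quantification; biological replicates stay separate.
Quantities are normalized per sample by the arithmetic mean (geometric
optional — the literature says only "average") of the reference-gene
quantities.

## The synthetic-data generator

The generator plants the structure the analysis is supposed to find,
with full ground truth, at desk scale (defaults: 2000 genes, ten
clusters sized proportionally to a ~6700-gene DEG set, three cultivars
× 11 dates × 3 replicate trees ≈ 99 RNA-seq samples, one held-out qPCR
cultivar).

**Latent model.** Each cluster has a Gaussian-bump activity profile
(width 21 days) peaking at a stage-specific day between mid-July and
mid-March; the last cluster is bimodal (a summer peak at 0.8 relative
weight beside its spring peak), a profile type seen in dormancy time
courses that also separates it from the neighbouring late-winter
cluster. A gene's abundance is
`exp(base + ε) · (1 + amp · bump(τ − peak − jitter)) · warp · wiggle`:
the bump acts affinely (peak/baseline fold change 1 + amp, amp ~
U(4, 9)), so all members of a cluster share one z-profile shape up to
their deviations.

**Cultivar timing.** Until endodormancy onset (1 October) all cultivars
traverse the same trajectory — organogenesis and paradormancy are
synchronous. After onset, each cultivar progresses through a common
physiological time axis at rate (reference onset-to-release span)/(own
span), the chilling-requirement analogue, reaching the identical latent
state on its own release date; after release, ecodormancy progresses in
real time (growth resumption is temperature-driven and shared within
one orchard). Release dates (15 Dec / 15 Jan / 15 Feb for the training
cultivars; 1 Mar for the held-out cultivar) fall on sampling dates, so
each cultivar contributes exactly one sample inside its ±7-day release
window and stage classes occupy consistent positions along the
trajectory.

**Noise layers, and why each exists.**
- *Peak jitter* (N(0, 2.5 d), clipped at ±5 d): genes follow their
  cluster's timing imperfectly.
- *Gene warp* (a localized multiplicative bump, weight N(0, 0.25)
  clipped at ±0.4): systematic gene-specific deviation from the cluster
  trend, identical across replicates and cultivars. Clipping matters:
  heavy warp tails make complete linkage split large clusters rather
  than keep small ones separate.
- *Date wiggle* (lognormal, sd 0.22 per gene×date, shared by all trees
  and cultivars): weather-driven fluctuation of the transcriptome at a
  calendar date. Because replicate averaging cannot remove it, genes
  with a large wiggle are genuinely worse cluster representatives —
  this is what makes the planted markers (wiggle 0, jitter 0, warp 0,
  per-sample noise 0.05, high expression, top amplitude) identifiable
  as the best centroid correlates.
- *Per-sample noise* (lognormal, sd 0.12) and *counts* (negative
  binomial, dispersion 100, library sizes U(8–12 M)): tight biological
  replicates, as season-long bud time courses show.

**Annotations** are Bernoulli(0.10) background memberships; planted
(cluster, set) pairs carry 5× the background rate inside their cluster.
**Bud break** is a logistic curve (scale 6 days) crossing 50 % at the
planted release date, observed fortnightly as binomial counts over 30
buds. **qPCR** converts held-out-cultivar latent marker profiles to Cq
through planted standard curves (slope ≈ −3.32, i.e. ~100 %
efficiency) with 20 % multiplicative expression noise and Cq noise
sd 0.2 (two technical replicates); two flat reference genes are
included. All outputs derive from independent RNG streams spawned from
one seed, so every artifact is reproducible in isolation.

**What the generator does not emulate.** Real libraries have tens of
thousands of genes, most of them filtered out; here every gene belongs
to a planted cluster, so the expression filters are exercised on unit
fixtures rather than the synthetic run. There is no batch structure, no
isoform complexity, no annotation-ontology hierarchy, and the latent
trajectory is exactly one-dimensional (phase). Passing the end-to-end
tests therefore shows the algorithms recover the structure they assume,
not that real buds satisfy those assumptions.

## Problem sizes and determinism

The default synthetic analysis (2000 genes, 99 samples) runs in a few
seconds; repeated train/test evaluation uses 50 splits in the tests and
the acceptance script — the repeated-split estimate is stable well
below that, and the split count is a parameter for users who want the
convention of larger designs (500). All stochastic steps take explicit
seeds; cross-validation folds are deterministic given the fitted
estimator's `cv_random_state`.

## Known limitations

- The DE stand-in under-calls boundary-peaking genes (see above); it is
  calibrated (≈5 % raw-p rejections under exchangeability) but not a
  count model.
- Marker recovery depends on cluster-label alignment: when the two tiny
  early-season clusters merge under complete linkage, chronological
  labels shift by one and the fixed chosen-cluster set selects from
  neighbouring clusters. Across seeds the panel recovers 5–7 of the 7
  planted markers most of the time, occasionally fewer.
- Cross-platform accuracy is intrinsically below 1 even without noise:
  October-normalized TPM ratios carry the library-composition factor
  while absolute qPCR quantities do not, and paradormancy — the one
  stage in which no marker cluster peaks — borders endodormancy in
  marker space. Dormancy time-course studies report the same two
  effects (paradormancy is the least predictable stage).
- The hypergeometric tests are exact but conservative for discrete
  counts; p-values are valid, not uniform, under the null.
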