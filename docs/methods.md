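# Methods

## Model and scope

`progdyn` analyses ordered histological stage courses of gene expression.
All computations assume the input matrix is already normalized and
log2-scaled (for microarrays, the output of RMA-style preprocessing; for
RNA-seq, log2 of normalized counts); the loaders never transform values.
Stages are ordered with the reference (normal) stage first and the tumor
stage last; the dynamic partition is defined for exactly four stages
(three progression steps), while fold-changes, enrichment scoring, rates,
and all downstream analyses work for any design with ≥ 2 stages or classes.

## Fold-changes and the dynamic partition

Differential expression is defined purely by fold-change, with no
variance-based or moderated statistic: on the log2 scale, FC(a vs b) is the
difference of per-stage means, and a gene is differentially expressed when
|FC| exceeds a strict threshold (default 1.0 log2 units, i.e. two-fold).
This is deliberate at the emulated design size (3 replicates per stage),
where per-gene variance estimates are unstable.

Partition rules, in order:

1. TGS gate: a gene must satisfy |FC(tumor vs normal)| > threshold to enter
   any subset. A gene that crosses the threshold at some step but not
   overall belongs to no set.
2. Earliest-step assignment: within the TGS, a gene joins EGS/IGS/LGS at
   the first step whose |step FC| exceeds the threshold.
3. Progressive fallback: a TGS gene with no threshold-crossing step is PGS.
4. Direction: up/dn follows the sign of the tumor-vs-normal FC for all five
   sets, so the subset UP/DN lists are sub-lists of the TGS ones. A gene
   whose defining-step FC sign disagrees with its overall sign is kept
   (overall-sign convention) but listed in `sign_conflicts`, because no
   convention for this corner case is canonical; surfacing beats silently
   resolving.

Ortholog projection maps every member through a one-to-many source→target
table, collapsing duplicates and dropping (and counting) unmapped members.
Many-to-many maps can create collisions the partition invariants forbid;
both are resolved deterministically and reported: a target claimed by
several subsets stays in the earliest (EGS < IGS < LGS < PGS), and a target
claimed with both directions is dropped as ambiguous. The projected TGS is
rebuilt as the union of the projected subsets so the partition invariants
hold by construction.

## Enrichment scoring

ssGSEA replaces a sample's values by ranks N..1 (highest expression first)
and sums, over all rank positions, the difference between the weighted ECDF
of in-set genes (weight = rank^α) and the unweighted ECDF of out-of-set
genes. Defaults and conventions:

* α = 0.25, the convention of the widely used ssGSEA projection tool;
  α = 0 weights all in-set genes equally.
* Ties in expression are broken by gene identifier after the value sort, so
  scores are bitwise reproducible.
* Scores are left unnormalized (no division by a null mean); the pipeline
  only ever compares scores across samples of one dataset, and any affine
  rescaling cancels in the enrichment-rate statistic and in rank-based
  downstream tests.
* Combined score of an UP/DN family = ES(UP) − ES(DN). The combination rule
  is a package convention (stated, tested, antisymmetric under swapping the
  two sets).

Preranked GSEA uses the classic weighted Kolmogorov–Smirnov running sum
(hit increments |score|^p normalized over in-set genes, default p = 1;
uniform miss decrements) and reports the signed maximal deviation. The
nominal p-value is the fraction of `n_perm` random same-size gene sets,
drawn from the ranked universe with a seeded generator, whose score has the
observed sign and at least the observed magnitude. Gene-set permutation is
the only null that is well defined for an externally ranked list — there
are no phenotype columns left to permute — which is why it is the standard
null of preranked mode; effective set-size bounds default to 15–500 and can
be overridden. If every in-set ranking score is exactly zero the hit
weights degenerate; the scorer then falls back to equal weights rather than
dividing by zero.

## Enrichment rate

Stage-level score = arithmetic mean of the per-sample ES over that stage's
replicates (the natural aggregation for a replicated design; the package
does not smooth or monotonize the stage course). rate_k = |Δ_k| / |Δ_total|
with Δ_total = ES(tumor) − ES(normal). Rates are reported raw: on a
non-monotone course individual rates can exceed 1 and need not sum to 1,
but signed deltas always telescope exactly to the total. A zero total delta
makes the rate undefined and raises a named error rather than returning
NaN. Rates are reported for combined UP−DN scores by default; passing an
uncombined ES matrix gives per-direction rates.

## Synthetic-data generators

The generators define the study conditions the tests and the acceptance
checks run under; they are first-class, tested code.

* **Stage course** — 4 stages × 3 replicates by default, mirroring the
  microdissected mouse design the pipeline targets. Non-null genes shift by
  a full `effect` (default 2.0 log2 units) with archetype profiles: early
  from hyperplasia onward, intermediate from dysplasia, late at tumor only,
  progressive linearly (k/3 of the effect at stage k — so with effect < 3
  each per-step FC is below a 1.0 threshold by construction, which is the
  progressive concept). Half of each archetype's genes go up, half down.
  Per-gene baselines are uniform on 5–10 log2 units; noise is i.i.d.
  Gaussian (default SD 0.2, a plausible replicate SD for arrays) per
  gene × sample, with no gene–gene correlation — the simplest model under
  which the FC-threshold partition is well defined.
* **Cohort** — normal/dysplasia/tumor class sizes default to 45/17/169,
  the composition of a public OSCC cohort the clustering analysis
  emulates; set members shift by ±effect in tumor, half in dysplasia
  (default effect 3.0, noise SD 0.5).
* **Survival** — exponential proportional hazards, hazard =
  baseline_hazard · hr_per_unit^score, independent exponential censoring.
  Proportional hazards holds exactly, so Cox recovery and CI coverage are
  clean parameter-recovery checks.
* **Drug response** — log-IC50 = −r·z(score) + sqrt(1 − r²)·noise, giving
  expected Pearson correlation −r with the score; the power check uses
  r = 0.6 at n = 51 cell lines, the panel size of the emulated screen.

What the generators do **not** emulate: probe-level effects, batch
structure, heavy-tailed or count noise, gene–gene correlation, informative
censoring, or shared-target correlation structure across drugs. Passing
tests therefore demonstrate correctness of the statistics and recovery
under the stated model, not robustness to real-data artifacts.

## Statistical components

* Fisher's exact test: 2×2 via the hypergeometric distribution; r×c tables
  (r, c ≤ 4, total ≤ 500) by exact enumeration of all fixed-margin tables,
  summing probabilities ≤ the observed table's (with a 1e−7 relative slack
  when comparing probabilities, the convention of mainstream statistical
  software); larger tables by a seeded Monte-Carlo over random fixed-margin
  tables with the +1/(n+1) estimator. Dense 4×4 tables near the total
  bound enumerate many tables and can be slow; the printed tables this
  pipeline meets are 2×2 and 2×3.
* Correlation screens report Pearson r with the two-sided p of the
  t transform (n − 2 df), drop missing pairs per feature, record
  zero-variance features as missing rather than erroring, and flag hits at
  unadjusted p < 0.01 — matching how such screens are reported — with a
  Benjamini–Hochberg q column added for transparency only. IC50 inputs are
  expected on the log scale (IC50 is multiplicative).
* Group comparisons: Student's t, Mann-Whitney (exact when combined
  n ≤ 20 without ties, tie-corrected normal approximation otherwise),
  one-way ANOVA, Kruskal-Wallis.
* Clustering: distance = 1 − Pearson correlation between sample profiles on
  the set-restricted matrix, Ward linkage, tree cut at 2. Ward linkage on a
  correlation distance is not Euclidean-metric Ward, but it is the
  field-standard pairing for expression heatmaps and is used as such.
  Cluster label 1 is the cluster with the higher mean combined set score, a
  deterministic orientation (for a tumor set, cluster 1 reads "tumor-like").
* PCA: mean-centered, full SVD, each component's sign fixed so its
  largest-magnitude loading is positive.
* Survival: Kaplan–Meier estimates, k-group log-rank (chi-square, k − 1
  df), reverse Kaplan–Meier median follow-up, and Cox partial likelihood
  with Efron tie handling (lifelines), with categorical covariates
  dummy-coded against a declared reference level (tertile reference =
  "low", so hazard ratios read high-vs-low). Tertile cuts are the
  interpolated empirical 1/3 and 2/3 quantiles with ties assigned to the
  lower group — the tie rule is a package convention.

## Numerical and design notes

* All stochastic operations take an explicit seed; there is no global
  default randomness. Fixed seed + fixed config = byte-identical outputs.
* The FC threshold is strict (> 1.0), so a gene at exactly the threshold is
  not differentially expressed.
* The noise-free single-archetype stage course is the reference case for
  the rate statistic: an early-only course yields rates exactly (1, 0, 0)
  because samples after the defining step are identical; a
  progressive-only course yields rates ≈ 1/3 each, approximately rather
  than exactly, because ssGSEA depends on ranks and the linear mean shift
  translates to per-step rank displacements only up to discreteness (with
  uniform baselines the deviation is a few hundredths at 230 genes). With
  several archetypes in one matrix, later-stage movements of other genes
  perturb a set's ranks after its defining step, so stage-specific rates
  concentrate at, but not exactly on, the defining step.
* Simulation sizes used by the test suite and the acceptance script
  (20 stage-course seeds, 2000 null simulations per calibration, 200 Cox
  fits at n = 300, 100 drug-screen seeds) keep the whole run in a few
  minutes on one CPU while leaving Monte-Carlo error well inside the
  asserted bands.

## Known limitations

* Under the default recovery conditions (effect 2.0, noise SD 0.2,
  3 replicates), a progressive gene's per-step FC margin is
  (1 − 2/3) = 1/3 at a step-FC SD of 0.2·√(2/3) ≈ 0.163, so each step
  exceeds the threshold with probability ≈ 2%, and ≈ 6% of progressive
  genes are misassigned to a step subset — progressive recovery sits near
  94%, not at the ≥ 95% of the other archetypes. This is a property of the
  strict FC rule at these settings, not an implementation artifact; larger
  replicate numbers or smaller noise move it to ~100%.
* The partition is gene-level; probe-to-gene collapsing for real array
  annotations is out of scope, as are normalization, batch correction, and
  any cohort downloading.
* No NES/FDR machinery for catalog-scale GSEA runs, no proportional-hazards
  diagnostics, time-varying covariates, or competing risks.
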