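# progdyn

Stage-wise dynamics of gene-expression changes in tumor progression.

Carcinogen-driven epithelial cancers develop through an ordered sequence of
histological stages — normal mucosa → hyperplasia → dysplasia → invasive
tumor. Knowing *when* along that sequence each expression change is acquired
matters for chemoprevention (early changes mark risk in premalignant
lesions) and for treatment (late or progressive changes mark tumor biology
and drug sensitivity). `progdyn` implements that analysis as a reusable,
tested pipeline for anyone with a log2 expression matrix and ordered stage
labels — e.g. from a 4-NQO mouse model of oral tumorigenesis projected onto
human oral squamous cell carcinoma cohorts.

## What it computes

**Dynamic gene-set partition.** With per-stage mean log2 expression, the
log2 fold-change between stages a and b is FC = mean_a − mean_b. The tumor
gene set is

    TGS = { g : |FC_tumor-vs-normal(g)| > 1 },

split into UP and DN by the sign of the overall FC. The TGS is then divided
into four non-overlapping subsets by the **first** progression step whose
|FC| exceeds the same threshold: EGS (early; hyperplasia vs normal), IGS
(intermediate; dysplasia vs hyperplasia), LGS (late; tumor vs dysplasia),
and PGS (progressive; TGS genes that never cross the threshold at any
single step — changes acquired gradually).

**Single-sample enrichment (ssGSEA).** A sample's expression values are
rank-normalized (ranks N..1, highest first) and a gene set's enrichment
score is the sum of differences between the weighted ECDF of in-set genes
(weight rank^α, α = 0.25 by default) and the ECDF of the remaining genes.
For an UP/DN set family the combined score is ES(UP) − ES(DN). A classic
preranked GSEA (weighted Kolmogorov–Smirnov statistic with a random-gene-set
null) is included for externally ranked lists.

**Enrichment rate.** For each gene set and step,

    rate_k = |ΔES(step_k)| / |ΔES(tumor − normal)|,

where stage-level ES is the replicate mean — the fraction of the total
tumor-vs-normal enrichment acquired at step k. A set specific to one stage
concentrates its rate in one step; a progressive set spreads it evenly.

**Downstream associations.** Two-way hierarchical clustering (1 − Pearson
distance, Ward linkage) of cohort samples on a gene set, with cluster ×
histology Fisher exact tests (exact enumeration for r×c tables); PCA
projections; Pearson correlation screens of enrichment scores against
pathway-score or drug log-IC50 panels (screen threshold p < 0.01, negative
correlations flagged as drug sensitivity); t / Mann-Whitney / ANOVA /
Kruskal-Wallis group comparisons; and score-tertile survival analysis
(Kaplan–Meier, log-rank, univariate and covariate-adjusted Cox models with
Efron tie handling).

**Synthetic data.** Every input has a generator with planted truth: a
4-stage × 3-replicate course with early/intermediate/late/progressive/null
genes, a normal/dysplasia/tumor cohort, exponential proportional-hazards
survival times driven by a score, and log-IC50 vectors with a controlled
correlation to a score. These make every downstream claim testable without
any external download.

## Worked example

```python
import progdyn as pg

matrix, truth = pg.generate_stage_course(n_per_archetype=100, effect=2.0,
                                         noise_sd=0.2, seed=42)
design = pg.stage_course_design(matrix)
fc = pg.compute_fold_changes(matrix, design)
part = pg.partition_dynamics(fc, design, threshold=1.0)
print({name: len(ds) for name, ds in part.as_dict().items()})

es = pg.ssgsea_matrix(matrix, part.to_gene_sets(), combine=True)
rates = pg.rate_profile(es, design, set_names=["EGS", "IGS", "LGS", "PGS"])
cols = ["hyperplasia_vs_normal", "dysplasia_vs_hyperplasia", "tumor_vs_dysplasia"]
print(rates.pivot(index="set", columns="step", values="rate")[cols].round(2))

scores = es.loc["EGS"]
surv = pg.generate_survival(scores, hr_per_unit=3.0, baseline_hazard=0.05,
                            censor_rate=0.02, seed=42)
km = pg.km_logrank(surv, pg.tertile_groups(surv["score"]))
print(f"log-rank chi2 = {km.chi2:.2f}, p = {km.p:.4f}")
```

prints

```
{'TGS': 400, 'EGS': 102, 'IGS': 101, 'LGS': 101, 'PGS': 96}
step  hyperplasia_vs_normal  dysplasia_vs_hyperplasia  tumor_vs_dysplasia
set
EGS                    1.18                      0.06                0.12
IGS                    0.00                      1.08                0.08
LGS                    0.01                      0.00                1.01
PGS                    0.42                      0.34                0.24
log-rank chi2 = 16.84, p = 0.0002
```

The 400 planted informative genes are recovered into a 400-gene TGS and the
four subsets match their archetypes almost perfectly (a handful of
progressive genes whose noisy step FC crosses the threshold land in a step
subset). Each stage-specific subset acquires essentially all of its
enrichment at its defining step (rates ≈ 1 on the diagonal), while the
progressive subset spreads its enrichment across all three steps. Tertiles
of the early-subset score strongly separate the simulated survival curves,
as built into the generator.

The same analyses are scriptable from the shell via the `progdyn` CLI
(subcommands `simulate`, `partition`, `score`, `rate`, `associate`,
`survive`); each run writes its outputs as TSV/CSV plus a `*.meta.json`
sidecar recording parameters, seed, and version.

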