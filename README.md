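# igeprs

Leave-one-group-out polygenic risk scores for total serum IgE, and
model-based clustering of asthma phenotypes.

Asthma is heterogeneous: total serum IgE can be elevated through allergic
sensitization, through environmental exposures such as smoking, or through
an intrinsic genetic predisposition to IgE production. `igeprs` is for
genetic epidemiologists who want to separate those routes: it builds a
polygenic risk score (PRS) for log10 total IgE in non-asthmatic controls,
transfers the score to an asthma cohort, clusters the cases on
(IgE PRS z, log IgE, onset age, percent-predicted FEV1) with automatic
selection of the cluster count, and classifies newly developed asthma cases
by nearest centroid. Individual-level cohorts of this kind cannot be
redistributed, so the package includes a synthetic cohort generator with
the same statistical structure (LD-blocked genotypes in Hardy-Weinberg
proportions, additive genetic effects on log IgE, covariate effects,
missing data, related pairs, and a planted four-component case mixture),
making the whole pipeline testable without any download.

## The score

Within the reference (control) cohort, samples are split into K = 5 random
subgroups. For each fold *i*, a covariate-adjusted GWAS of log10 IgE is run
on the other four subgroups; summary statistics are LD-clumped
(r² ≥ 0.1 within 250 kb) and p-value-thresholded, with the threshold chosen
to maximize the incremental R² in the held-out subgroup. Each fold's score
is the mean weighted dosage

    PRS_j = (1 / M_j) · Σ_i S_i · G_ij

(S_i = per-effect-allele GWAS estimate, G_ij = effect-allele dosage, M_j =
number of non-missing scored SNPs), and the five scores per individual are
combined by fixed-effect inverse-variance meta-analysis

    IgE_PRS = Σ_i (PRS_i / SE_i²) / Σ_i (1 / SE_i²),

with SE_i from the held-out PRS–IgE regression of fold i, then z-scored
against the reference cohort (mean 0, SD 1 by construction). Upstream, the
package provides standard GWAS quality control (call rate, MAF, exact
Hardy–Weinberg test, heterozygosity outliers, KING-robust relatedness) and
genotype PCA; downstream, SPSS-style two-step clustering with BIC-based
automatic selection of k, silhouette diagnostics, nearest-centroid
classification, and the group-comparison battery (chi-square,
Kruskal–Wallis, Dunn–Bonferroni, covariate-adjusted regression).
See `docs/methods.md` for the full model description, including two caveats
worth knowing before interpreting results: the combined score mixes
in-sample fold scores (use `LogoResults.heldout_scores` for out-of-sample
diagnostics), and the reported clustering silhouette comes in both the
classic pairwise and the center-based (two-step-tool) variants.

## Worked example

```python
import numpy as np
from igeprs import (SimConfig, simulate_reference_panel, simulate_phenotypes,
                    IgePrsLogo, TwoStepCluster)
from igeprs.simulate import draw_cluster_features

cfg = SimConfig(n_controls=1000, n_cases=745, n_snps=2000, n_blocks=100, seed=7)
genotypes, truth = simulate_reference_panel(cfg)
cohort = simulate_phenotypes(genotypes, truth, cfg)

results = IgePrsLogo(genotypes, cohort, k=5, n_pcs=5).fit(seed=7)
print(results.summary())
```

```
LOGO IgE PRS results
====================
samples: 1000   folds: 5   seed: 7
reference z-score: mean -0.00, SD 1.00
combined score vs phenotype R2: 0.205

fold  threshold  n_snps        SE  heldout_dR2
   1       0.05      67    5.1686       0.2411
   2       0.01      27    3.2526       0.1226
   3     0.0001       7    1.1994       0.0845
   4      0.001      14    1.8293       0.1517
   5       0.01      32    2.6209       0.2288
```

Each fold picked its own p-value threshold (here between 1e-4 and 0.05,
retaining 7–67 SNPs); the combined, z-scored IgE PRS explains 20.5% of the
log-IgE variance in this simulated cohort (heritability 0.30), and the
reference z-scores are standardized by construction. Clustering the default
four-component case mixture:

```python
_, features = draw_cluster_features(cfg, np.random.default_rng(4))
clusters = TwoStepCluster(features, k_max=15).fit(seed=4)
print(clusters.summary())
```

```
Two-step clustering results
===========================
features: prs_burden_z, log_ige, onset_age, pfev1
selected k: 4   silhouette: 0.202 (center-based 0.316)   rows dropped (missing): 0
cluster sizes: 1: 168, 2: 169, 3: 199, 4: 209
```

The BIC/merge-distance rule selects four clusters, numbered in descending
order of mean IgE PRS; the center-based silhouette (~0.3) is the measure
two-step clustering tools report, the classic pairwise value (~0.2) is
lower on these overlapping components. The mixture components overlap
substantially, so on a minority of draws the selection rule's null guard
reports a single cluster instead — the modal choice over repeated draws
is four. A full synthetic run — QC, LOGO PRS
on controls, external scoring of cases, clustering, centroid fit, group
statistics — is one call (`igeprs run-all --out run --seed 1` on the
command line, or `run_pipeline(RunConfig(...))` from Python) and takes
about two minutes at the default 1,287 + 745 samples × 10,000 SNPs.

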