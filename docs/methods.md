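# Methods

`igeprs` implements a genetic-epidemiology pipeline for dissecting asthma
heterogeneity by genetic predisposition to elevated total serum IgE: a
leave-one-group-out (LOGO) polygenic risk score (PRS) for log10 total IgE
built in non-asthmatic controls, transfer of that score to an asthma cohort,
model-based clustering of the cases, and nearest-centroid classification of
newly developed cases. Because individual-level cohorts of this kind cannot
be redistributed, the package ships a synthetic cohort generator that
reproduces the statistical structure the pipeline assumes, so every stage is
testable end to end.

## Quality control

Sample-level rules: missingness > 10%; heterozygosity beyond +/- 3 SD of the
cohort mean (mean and SD computed once over samples passing the missingness
filter — a single pass, no iteration); relatedness above the second-degree
KING-robust bound (0.0884). The pairwise kinship estimator is

    phi_hat = (N_both_het - 2 N_opposite_hom) / (N_het(i) + N_het(j)),

counted over SNPs non-missing in both samples; duplicates give ~0.5,
parent-offspring pairs ~0.25, unrelated pairs ~0. One member of each flagged
pair is removed (higher missingness first; ties remove the later sample).
The null sampling noise of phi_hat scales with the effective number of
independent markers: with ~5,000 independent SNPs unrelated pairs stay
within +/-0.02, but panels of a few hundred SNPs produce spurious
second-degree hits, so the threshold should only be applied to panels of at
least ~1,000 markers.

SNP-level rules: call rate < 0.99, MAF < 0.01, exact Hardy-Weinberg
p < 1e-6. The HWE test is the exact conditional test (no mid-p): the
p-value sums the conditional probabilities of all heterozygote counts, of
the same parity and consistent with the observed allele counts, whose
probability does not exceed the observed one. It is computed with the
standard probability recurrence and agrees with exact-rational enumeration
to 1e-12 for all n <= 50 (asserted in the tests).

## Association scans and PCA

Quantitative scans fit least squares of the phenotype on effect-allele
dosage plus covariates (age, sex, two smoking-category indicators, atopy,
and genetic principal components), taking beta/SE/p from the dosage
coefficient with t inference on the residual degrees of freedom. SNPs with
complete dosages go through a Frisch-Waugh residualization fast path that is
algebraically identical to the full fit; SNPs with missing calls are fit on
their complete cases. The case-control scan is the covariate-free 1-df
allelic chi-square on the 2x2 allele-count table, with the log allelic odds
ratio as the effect.

PCA standardizes each SNP to (G - 2p)/sqrt(2p(1-p)), zero-fills missing
entries after centering, and takes the top-k left singular vectors
(randomized SVD for large inputs, dense SVD below 200 x 200, signs fixed by
the largest-magnitude loading). Held-out samples are projected with the
training-set frequencies and loadings; no refitting, hence no leakage of
held-out genotypes into the fold's covariates.

## PRS construction (clumping + thresholding, LOGO)

The per-individual score is the mean weighted dosage
PRS_j = (1/M_j) sum_i S_i G_ij, where S_i is the GWAS effect for the effect
allele of SNP i and M_j counts the SNPs with a non-missing genotype in
individual j; allele flips (effect/other swapped) enter as 2 - G. Candidate
SNPs come from greedy LD clumping (ascending p; each index SNP removes
candidates within 250 kb at dosage r^2 >= 0.1; ties broken by position then
id), followed by p-value thresholding over the grid
{5e-8, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0}. The
threshold maximizes the incremental R^2 of the score over a covariate-only
regression in the held-out target subgroup (covariate-adjusted rather than
marginal; an empty covariate table gives the marginal variant).

The LOGO build splits the reference cohort into K = 5 random, near-equal
folds. Per fold: GWAS on the other four folds (PCs computed on those
samples and projected onto the held-out fold), clumping, threshold
optimization on the held-out fold, then scoring of all samples with that
fold's model. The K scores are combined per individual by fixed-effect
inverse-variance weighting, IgE_PRS = sum_i PRS_i/SE_i^2 / sum_i 1/SE_i^2,
where SE_i is the standard error of the PRS coefficient in the held-out
covariate-adjusted regression of fold i (out-of-sample weights). The
combined score is z-scored against the reference-cohort mean and SD, which
makes the reference summary 0.00 (1.00) by construction; external cohorts
are scored with the same fold models, fold SEs and z reference.

A property of this construction worth stating plainly: because each fold's
model also scores the samples its GWAS was trained on, four of the five
per-individual scores are in-sample, and the combined score retains overfit
association even for a heritability-zero phenotype (we measure null R^2
between ~0.01 and ~0.15 depending on how many SNPs the null threshold search
retains). `LogoResults.heldout_scores` therefore exposes the fully
out-of-sample score — each individual scored only by the one model fit
without them — which is null-calibrated (R^2 <= 0.003 in our null runs) and
is the right quantity for overfitting diagnostics. The combined score is
kept as the pipeline's primary output because it is the published
construction; its apparent variance explained should be read with this
caveat.

## Two-step clustering with automatic k

Cases are clustered on four features in this order: IgE_PRS z, log10 IgE,
asthma onset age (years), and percent-predicted FEV1. Features are
standardized to z-scores; rows with any missing feature are dropped with a
count. Stage 1 is a single-level sequential preclustering pass with an
automatically growing log-likelihood-distance threshold, capped at 1,024
preclusters. For inputs at or below the cap (including cohort-scale case
sets) stage 1 is the identity and the procedure is direct agglomeration,
which is invariant to the point-processing order; sequential compression is
kept for larger inputs, where it is audited against direct agglomeration in
the tests. The cap sits above typical cohort sizes deliberately: near the
selection boundary the compressed path can make the chosen k depend on the
seeded processing order, which is undesirable for a reported cluster
count. Stage 2 agglomerates by the log-likelihood distance
d(i,j) = xi_i + xi_j - xi_{i+j} with
xi_v = -n_v sum_d 0.5 log(sigma2_d + sigma2_vd), where sigma2_d is the
overall per-feature variance (a regularizer) and sigma2_vd the within-
cluster ML variance. BIC(k) = -2 sum_v xi_v + 2 k d log N.

Automatic k uses a coarse BIC pass refined by merge-distance ratios: k_init
is the smallest k whose BIC change dBIC(k) = BIC(k+1) - BIC(k) falls below
0.04 x dBIC(1) (k = 1 if BIC does not improve from one to two clusters);
among 2 <= k <= k_init the candidate with the largest ratio of successive
merge distances R(k) = m_k/m_{k+1} wins, taking the larger k when the top
two ratios are within 15%. Hard-assignment likelihoods always improve under
splitting, so BIC alone cannot return k = 1 on homogeneous data; we
therefore add a null-calibrated guard: if no R(k) exceeds 1.9 — the ~99th
percentile of the largest ratio over 100 homogeneous-Gaussian runs at
n = 400..1000, d = 4 — the profile is declared structureless and k = 1 is
returned. The guard trades ~1% false "one cluster" calls on genuinely
structured data for reliable null behavior.

Labels are renumbered in descending order of the first feature's cluster
mean, so cluster 1 always has the highest mean IgE_PRS.

Two silhouette measures are reported. `silhouette_index` is the classic
pairwise mean silhouette (singletons contribute 0), used for oracle tests.
`silhouette_centers` is the center-based cohesion/separation variant that
two-step clustering tools report (distance to own centroid vs nearest other
centroid); it is systematically higher on overlapping clusters and is the
measure that reproduces the familiar "~0.3 for a fair four-cluster
solution" scale on our default case mixture (center-based mean 0.31 vs
classic 0.19 over 20 seeds). When comparing against silhouettes quoted from
two-step tools, use the center-based one.

## Nearest-centroid assignment

Centroids are per-cluster means in the standardized feature space, with the
standardization parameters copied from the clustering build (not refit on
new cases — unstandardized Euclidean distance would be dominated by the
age and pFEV1 scales). Every complete case receives a label (no
"unassignable" threshold); ties go to the lowest cluster index; rows with
missing features are reported unassigned.

## Statistics battery

Pearson chi-square without continuity correction (this is the convention
that reproduces the published cohort-table p-values to their printed
precision, verified by recomputation from the printed counts, using the
non-missing denominators from the tables' footnotes); Kruskal-Wallis with
tie correction; Dunn z post-hoc tests on mean ranks with tie-corrected
pooled variance and Bonferroni (not Holm) adjustment capped at 1;
covariate-adjusted linear regression for group comparisons (listwise
deletion); squared Pearson correlation with t-based p; and a routing gate
that returns "parametric" only when every group passes Shapiro-Wilk and
mean-centered Levene at the given alpha. Note the gate's expected
parametric rate on truly normal groups is (1 - alpha)^(g+1) for g groups
(about 81% for three groups at alpha 0.05), not 1 - alpha.

## Synthetic cohorts: what they emulate and what they do not

Genotypes use a block-diagonal latent-Gaussian threshold model: each
haplotype's latent vector is equicorrelated within 20-SNP blocks
(correlation calibrated by bisection of the bivariate-normal orthant
probability so the realized adjacent-SNP dosage correlation matches
`block_corr`, default 0.4), thresholded at the allele-frequency quantile.
Two independent haplotypes per individual give exact per-SNP Hardy-Weinberg
proportions. MAFs are uniform on (0.05, 0.5); missing calls are injected
completely at random (default rate 0.002) except for targeted QC artifacts
(high-missingness samples, exact duplicates, Mendelian parent-offspring
pairs, heterozygosity-inflated samples).

Phenotypes: log10 IgE = intercept + additive genetic value + covariate
terms + Gaussian noise, on a scale of mean 1.78 and SD 0.58 log10 IU/mL.
Fifty causal SNPs (one per block where possible) are rescaled so the
genetic variance fraction given covariates equals `h2` (default 0.30, a
moderate SNP heritability for a genotyping-array panel). Covariate
marginals are cohort-scale presets (51.4% female, mean age 51.3,
never/light/heavy smoking 55.8/13.0/31.2%, atopy 57.8% in controls; the
corresponding case-column values for cases), and covariate effects are
scale-matched defaults (female -0.10, +0.08 per smoking category, atopy
+0.45 log10 IU/mL) — the source material gives no environmental-exposure
model, so these are presets, not estimates.

Cases are drawn from a four-component mixture over (genetic IgE burden on
the control-standardized scale, log IgE, onset age, pFEV1). The default
preset uses the published cluster summaries for the log-IgE and pFEV1 means
and SDs and the onset means; onset SDs are derived from the printed ranges
(range/5, appropriate for n ~ 170 per cluster); burden shifts
(0.75, 0.25, -0.35, -0.55) with within-cluster SD 0.6 reproduce the
published overall case z summary (mean ~0.05, SD ~0.78). Case genotypes are
produced by exponentially tilting the causal-SNP allele frequencies per
individual (vectorized bisection) until the expected genetic value matches
the drawn burden; non-causal SNPs follow the control LD model.

Two deliberate limitations. First, a generative mixture with the published
within-cluster SDs overlaps more than the carved partition those SDs
summarize, so classic truth-label silhouettes are lower than published
cluster-solution silhouettes; truth-label silhouette reaches 0.3 only from
about 4 pooled-SD pairwise separation. Second, the planted burden is the
*true* genetic value, while the pipeline clusters on the *measured* PRS z;
measurement attenuates the burden separation (corr ~0.4 at h2 = 0.3), so
the full end-to-end run is not expected to re-find four clusters on the
measured scale — end-to-end tests check pipeline mechanics and calibration,
and cluster-recovery tests run on the drawn features. Passing tests
therefore demonstrate correctness of the machinery and calibration under
the stated generative conditions, not clinical validity on real cohorts.

## Problem sizes and numerics

Default analysis scale is 1,287 controls + 745 cases x 10,000 SNPs (a full
run takes about two minutes on one CPU); the LOGO calibration suites use
2,000 SNPs in 100 blocks with n = 1,000-1,500, sizes chosen to keep each
property measurable with comfortable margins. Degenerate cases: perfect
GWAS fits report p at the 1e-300 floor and SE 0; zero-variance or
under-observed SNPs yield NA rows; samples with no scored SNPs get NA
scores with a warning; a z reference with zero SD, empty clusters, single
clusters in silhouettes, and all-sample QC exclusion all raise informative
errors. All randomness flows from explicit integer seeds; equal seeds give
bit-identical outputs, including written files.
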