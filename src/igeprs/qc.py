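"""Sample- and SNP-level genotype quality control.

Exclusion rules follow standard GWAS practice: samples are dropped for
missingness > 10%, heterozygosity beyond +/- 3 SD of the cohort mean, or
close relatedness (KING-robust kinship above the second-degree bound);
SNPs are dropped for call rate < 0.99, MAF < 0.01, or exact
Hardy-Weinberg p < 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

KING_SECOND_DEGREE = 0.0884  # lower kinship bound for second-degree relatives


@dataclass
class QcConfig:
    sample_missing_max: float = 0.10
    het_sd_bound: float = 3.0
    kinship_threshold: float = KING_SECOND_DEGREE
    snp_call_rate_min: float = 0.99
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6

    def validate(self) -> None:
        for name in ("sample_missing_max", "kinship_threshold", "snp_call_rate_min",
                     "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"QcConfig.{name} must be in (0, 1)")
        if self.het_sd_bound <= 0:
            raise ValueError("QcConfig.het_sd_bound must be > 0")


@dataclass
class QcReport:
    """Exclusions with one primary reason code each, plus kept ids."""

    excluded: pd.DataFrame  # columns: id, reason
    kept: list = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def reasons(self) -> dict:
        return self.excluded.groupby("reason")["id"].apply(list).to_dict()

    def to_tsv(self, path) -> None:
        self.excluded.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- #
# sample QC
# --------------------------------------------------------------------- #
def heterozygosity_rate(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-sample heterozygous calls / non-missing calls."""
    d = genotypes.dosages
    het = np.nansum(d == 1, axis=1)
    nonmiss = np.sum(~np.isnan(d), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nonmiss > 0, het / nonmiss, np.nan)


def sample_qc(genotypes: GenotypeMatrix, config: QcConfig | None = None) -> QcReport:
    """Flag samples by missingness, then heterozygosity outliers.

    The heterozygosity mean/SD are computed once over the samples passing the
    missingness filter (no iteration). Each exclusion carries a single primary
    reason; missingness takes precedence.
    """
    config = config or QcConfig()
    config.validate()
    if genotypes.n_samples < 2:
        raise ValueError("sample_qc requires >= 2 samples")
    miss = genotypes.sample_missing_rate()
    miss_flag = miss > config.sample_missing_max

    het = heterozygosity_rate(genotypes)
    ref = het[~miss_flag]
    mu, sd = float(np.nanmean(ref)), float(np.nanstd(ref, ddof=1))
    if sd > 0:
        het_flag = (~miss_flag) & (np.abs(het - mu) > config.het_sd_bound * sd)
    else:
        het_flag = np.zeros_like(miss_flag)

    rows = []
    for i, s in enumerate(genotypes.samples):
        if miss_flag[i]:
            rows.append((s, "missingness"))
        elif het_flag[i]:
            rows.append((s, "heterozygosity"))
    excluded = pd.DataFrame(rows, columns=["id", "reason"])
    kept = [s for s in genotypes.samples if s not in set(excluded["id"])]
    if not kept:
        raise ValueError("sample QC excluded every sample; aborting")
    return QcReport(excluded=excluded, kept=kept)


# --------------------------------------------------------------------- #
# kinship
# --------------------------------------------------------------------- #
def kinship_matrix(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """KING-robust pairwise kinship estimates.

    phi_hat = (N_both_het - 2 * N_opposite_hom) / (N_het(i) + N_het(j)),
    counted over SNPs non-missing in both samples. Duplicates give ~0.5,
    parent-offspring ~0.25, unrelated ~0. Pairs with no heterozygous calls
    in either member are NaN.
    """
    d = genotypes.dosages
    H = (d == 1).astype(float)
    A = (d == 0).astype(float)
    B = (d == 2).astype(float)
    M = (~np.isnan(d)).astype(float)
    n_both_het = H @ H.T
    n_opp = A @ B.T + B @ A.T
    het_shared = H @ M.T  # het in i over SNPs non-missing in j
    denom = het_shared + het_shared.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_both_het - 2.0 * n_opp) / denom, np.nan)
    return pd.DataFrame(phi, index=genotypes.samples, columns=genotypes.samples)


def related_pairs(
    kinship: pd.DataFrame, threshold: float = KING_SECOND_DEGREE
) -> pd.DataFrame:
    """Upper-triangle pairs with kinship above the threshold."""
    ids = list(kinship.index)
    vals = kinship.values
    rows = [
        (ids[i], ids[j], vals[i, j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if np.isfinite(vals[i, j]) and vals[i, j] > threshold
    ]
    return pd.DataFrame(rows, columns=["id1", "id2", "kinship"])


def relatedness_qc(
    genotypes: GenotypeMatrix, config: QcConfig | None = None
) -> QcReport:
    """Flag one member of each related pair for removal.

    The member with higher missingness is removed; ties remove the sample
    that appears later in the matrix.
    """
    config = config or QcConfig()
    phi = kinship_matrix(genotypes)
    pairs = related_pairs(phi, config.kinship_threshold)
    miss = dict(zip(genotypes.samples, genotypes.sample_missing_rate()))
    order = {s: i for i, s in enumerate(genotypes.samples)}
    drop: set = set()
    for id1, id2, _k in pairs.itertuples(index=False):
        if id1 in drop or id2 in drop:
            continue
        if miss[id1] > miss[id2]:
            drop.add(id1)
        elif miss[id2] > miss[id1]:
            drop.add(id2)
        else:
            drop.add(id1 if order[id1] > order[id2] else id2)
    excluded = pd.DataFrame(
        [(s, "relatedness") for s in genotypes.samples if s in drop],
        columns=["id", "reason"],
    )
    kept = [s for s in genotypes.samples if s not in drop]
    return QcReport(excluded=excluded, kept=kept)


# --------------------------------------------------------------------- #
# exact HWE test
# --------------------------------------------------------------------- #
def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts; the p-value is the total
    probability of heterozygote counts (same parity) whose conditional
    probability does not exceed that of the observed count. Computed with the
    standard probability recurrence for numerical stability.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # attainable heterozygote counts share the parity of n_rare
    h_min = n_rare % 2
    h_max = min(n_rare, 2 * n - n_rare)
    hs = np.arange(h_min, h_max + 1, 2)
    if len(hs) == 1:
        return 1.0
    # unnormalized probs via recurrence:
    # P(h+2)/P(h) = 4 * n_r(h) * n_c(h) / ((h+2)*(h+1))
    # where n_r(h) = (n_rare - h)/2 rare homs, n_c(h) = (2n - n_rare - h)/2
    logp = np.zeros(len(hs))
    for k in range(1, len(hs)):
        h = hs[k - 1]
        n_r = (n_rare - h) / 2.0
        n_c = (2 * n - n_rare - h) / 2.0
        logp[k] = logp[k - 1] + np.log(4.0 * n_r * n_c) - np.log((h + 2.0) * (h + 1.0))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hs, n_het)]
    pval = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(pval, 1.0)


# --------------------------------------------------------------------- #
# SNP QC
# --------------------------------------------------------------------- #
def snp_qc(genotypes: GenotypeMatrix, config: QcConfig | None = None) -> QcReport:
    """Exclude SNPs failing call rate, MAF, or exact HWE thresholds.

    Reason precedence: call_rate, then maf, then hwe (one primary reason per
    SNP).
    """
    config = config or QcConfig()
    config.validate()
    if genotypes.n_samples < 2:
        raise ValueError("snp_qc requires >= 2 samples")
    call = genotypes.snp_call_rate()
    maf = genotypes.maf()
    counts = genotypes.genotype_counts()
    rows = []
    for j, snp in enumerate(genotypes.snps["id"]):
        if call[j] < config.snp_call_rate_min:
            rows.append((snp, "call_rate"))
        elif not np.isfinite(maf[j]) or maf[j] < config.maf_min:
            rows.append((snp, "maf"))
        elif hwe_exact_test(*counts[j]) < config.hwe_p_min:
            rows.append((snp, "hwe"))
    excluded = pd.DataFrame(rows, columns=["id", "reason"])
    bad = set(excluded["id"])
    kept = [s for s in genotypes.snps["id"] if s not in bad]
    return QcReport(excluded=excluded, kept=kept)


def apply_qc(
    genotypes: GenotypeMatrix, config: QcConfig | None = None, relatedness: bool = True
) -> tuple[GenotypeMatrix, dict]:
    """Sample QC, optional relatedness QC, then SNP QC; returns kept matrix."""
    config = config or QcConfig()
    srep = sample_qc(genotypes, config)
    g = genotypes.take_samples(srep.kept)
    reports = {"sample": srep}
    if relatedness:
        rrep = relatedness_qc(g, config)
        g = g.take_samples(rrep.kept)
        reports["relatedness"] = rrep
    vrep = snp_qc(g, config)
    g = g.take_snps(np.asarray(vrep.kept, dtype=object))
    reports["snp"] = vrep
    return g, reports
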