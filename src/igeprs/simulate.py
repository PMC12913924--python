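"""Synthetic genotype-phenotype cohorts for the IgE PRS / asthma-cluster analysis.

The generator emulates the statistical structure the downstream pipeline
assumes: LD-blocked biallelic genotypes in Hardy-Weinberg proportions,
additive genetic effects on log10 total serum IgE, covariate effects (sex,
age, smoking category, atopy), completely-at-random missing calls, optional
QC artifacts (high-missingness samples, duplicates, parent-offspring pairs,
heterozygosity-inflated samples), and a planted four-component case mixture
over (genetic IgE burden, log IgE, asthma onset age, percent-predicted FEV1).

Genotypes are produced by a latent-Gaussian threshold model: within each LD
block the two haplotypes of an individual are drawn from an equicorrelated
Gaussian and thresholded at the allele-frequency quantile, which yields exact
per-SNP Hardy-Weinberg proportions and a tunable adjacent-SNP correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

# Cohort-scale presets: control / case covariate marginals on the scale of a
# middle-aged Japanese health-checkup cohort (female fraction, mean age,
# never/light/heavy smoking fractions, aeroallergen sensitization fraction).
CONTROL_MARGINALS = {
    "female": 0.514,
    "age_mean": 51.3,
    "age_sd": 10.5,
    "age_range": (30.0, 84.0),
    "smoking": (0.558, 0.130, 0.312),
    "atopy": 0.578,
    "pfev1_mean": 92.4,
    "pfev1_sd": 12.5,
}
CASE_MARGINALS = {
    "female": 0.573,
    "age_mean": 58.3,
    "age_sd": 13.0,
    "age_range": (19.0, 90.0),
    "smoking": (0.605, 0.145, 0.250),
    "atopy": 0.704,
}

DEFAULT_COVARIATE_EFFECTS = {
    # log10 IU/mL per unit; female coded 1, smoking 0/1/2, atopy 0/1
    "sex": -0.10,
    "smoking": 0.08,
    "atopy": 0.45,
    "age": 0.0,
}


@dataclass
class ClusterComponent:
    """One planted case component: means/SDs of the four cluster features."""

    weight: float
    prs_z_mean: float
    prs_z_sd: float
    log_ige_mean: float
    log_ige_sd: float
    onset_mean: float
    onset_sd: float
    pfev1_mean: float
    pfev1_sd: float

    def validate(self, name: str) -> None:
        for f in ("prs_z_sd", "log_ige_sd", "onset_sd", "pfev1_sd"):
            if getattr(self, f) <= 0:
                raise ValueError(f"cluster_spec {name}: non-positive SD in field {f}")
        if self.weight < 0:
            raise ValueError(f"cluster_spec {name}: negative mixing weight")


def asthma_cluster_preset() -> list[ClusterComponent]:
    """Four-component case mixture at the scale of the adult asthma clusters.

    Component order follows descending genetic IgE burden: (1) adult-onset
    high-burden T2, (2) childhood-onset atopic, (3) smoking-associated
    late-onset obstructed, (4) oldest-onset non-T2. Means for log IgE, onset
    age and pFEV1 use the published cluster summaries; onset-age SDs are
    range-derived and burden shifts are set so the case mixture has a near-zero
    mean and sub-unit SD on the control-standardized scale.
    """
    rows = [
        # weight, prs_z, log_ige, onset, pfev1
        (199, (0.75, 0.60), (2.11, 0.54), (48.9, 15.0), (87.1, 19.9)),
        (157, (0.25, 0.60), (2.48, 0.52), (9.9, 6.5), (79.7, 20.7)),
        (178, (-0.35, 0.60), (2.47, 0.60), (49.2, 12.5), (64.7, 17.0)),
        (173, (-0.55, 0.60), (1.83, 0.61), (54.8, 13.5), (103.8, 17.1)),
    ]
    total = sum(r[0] for r in rows)
    return [
        ClusterComponent(w / total, *prs, *ige, *onset, *pfev)
        for (w, prs, ige, onset, pfev) in rows
    ]


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the analysis conditions: ~1,300 non-asthmatic controls
    and ~750 asthma cases, LD blocks of 20 SNPs with adjacent-SNP genotype
    correlation 0.4, 50 causal SNPs explaining ``h2`` of log-IgE variance on
    a phenotype scale of mean 1.78 / SD 0.58 log10 IU/mL.
    """

    n_controls: int = 1287
    n_cases: int = 745
    n_snps: int = 2000
    n_blocks: int = 100
    block_corr: float = 0.4
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 50
    h2: float = 0.30
    pheno_mean: float = 1.78
    pheno_sd: float = 0.58
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    cluster_spec: list = field(default_factory=asthma_cluster_preset)
    missing_rate: float = 0.002
    snp_spacing_bp: int = 5000
    blocks_per_chrom: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 1:
            raise ValueError("invalid SimConfig: n_controls must be >= 1")
        if self.n_cases < 0:
            raise ValueError("invalid SimConfig: n_cases must be >= 0")
        if self.n_snps < 1 or self.n_blocks < 1 or self.n_blocks > self.n_snps:
            raise ValueError("invalid SimConfig: need 1 <= n_blocks <= n_snps")
        if not (0.0 <= self.block_corr < 1.0):
            raise ValueError("invalid SimConfig: block_corr must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("invalid SimConfig: maf_range must lie in (0, 0.5]")
        if not (0 <= self.n_causal <= self.n_snps):
            raise ValueError("invalid SimConfig: n_causal must be <= n_snps")
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError("invalid SimConfig: h2 must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("invalid SimConfig: missing_rate must be in [0, 1)")
        if self.cluster_spec:
            w = sum(c.weight for c in self.cluster_spec)
            if abs(w - 1.0) > 1e-8:
                raise ValueError("invalid SimConfig: cluster_spec weights must sum to 1")
            for i, comp in enumerate(self.cluster_spec, 1):
                comp.validate(f"component {i}")


@dataclass
class TrueModel:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    causal_snp_ids: list
    causal_effects: np.ndarray  # per effect-allele copy, log10 IU/mL
    covariate_effects: dict
    intercept: float
    genetic_sd: float  # SD of the true genetic value in the reference panel
    allele_freqs: np.ndarray  # panel effect-allele frequencies, all SNPs
    latent_rho: float
    cluster_labels_truth: np.ndarray | None = None

    def to_json(self, path) -> None:
        d = asdict(self)
        for k in ("causal_effects", "allele_freqs", "cluster_labels_truth"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


# --------------------------------------------------------------------- #
# genotype generation
# --------------------------------------------------------------------- #
def _latent_rho_for(block_corr: float, maf: float) -> float:
    """Latent equicorrelation giving allele (phi) correlation ~= block_corr."""
    if block_corr <= 0:
        return 0.0
    t = stats.norm.ppf(maf)
    p, q = maf, 1.0 - maf

    def binary_corr(rho):
        joint = stats.multivariate_normal([0, 0], [[1, rho], [rho, 1]]).cdf([t, t])
        return (joint - p * p) / (p * q)

    lo, hi = block_corr, 0.9999
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if binary_corr(mid) < block_corr:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _snp_table(config: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """SNP metadata with block-contiguous 1-based positions; returns block ids."""
    block_sizes = np.full(config.n_blocks, config.n_snps // config.n_blocks)
    block_sizes[: config.n_snps % config.n_blocks] += 1
    block_of = np.repeat(np.arange(config.n_blocks), block_sizes)
    within = np.concatenate([np.arange(s) for s in block_sizes])
    # positions restart per chromosome, blocks laid end to end
    chrom = (block_of // config.blocks_per_chrom) + 1
    pos_counter = {}
    offsets = np.empty(config.n_blocks, dtype=int)
    for b in range(config.n_blocks):
        c = b // config.blocks_per_chrom
        offsets[b] = pos_counter.get(c, 0)
        pos_counter[c] = offsets[b] + block_sizes[b]
    pos = (offsets[block_of] + within + 1) * config.snp_spacing_bp
    snps = pd.DataFrame(
        {
            "id": [f"snp_{i:06d}" for i in range(config.n_snps)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
        }
    )
    return snps, block_of


def _draw_genotypes(
    n: int, freqs: np.ndarray, block_of: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Two latent-Gaussian haplotypes per individual, thresholded to alleles."""
    m = len(freqs)
    thresh = stats.norm.ppf(freqs)
    dos = np.zeros((n, m))
    for _ in range(2):  # two independent haplotypes -> exact HWE per SNP
        eps = rng.standard_normal((n, m))
        if rho > 0:
            shared = rng.standard_normal((n, block_of.max() + 1))
            z = np.sqrt(rho) * shared[:, block_of] + np.sqrt(1 - rho) * eps
        else:
            z = eps
        dos += z < thresh
    return dos


def simulate_reference_panel(config: SimConfig) -> tuple[GenotypeMatrix, TrueModel]:
    """Generate the control genotype panel and the causal ground-truth model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    snps, block_of = _snp_table(config)
    freqs = rng.uniform(*config.maf_range, size=config.n_snps)
    rho = _latent_rho_for(config.block_corr, float(np.mean(freqs)))
    dos = _draw_genotypes(config.n_controls, freqs, block_of, rho, rng)

    # causal SNPs spread over distinct blocks where possible
    if config.n_causal > 0:
        if config.n_causal <= config.n_blocks:
            blocks = rng.choice(config.n_blocks, size=config.n_causal, replace=False)
            causal_idx = np.array(
                [rng.choice(np.flatnonzero(block_of == b)) for b in blocks]
            )
        else:
            causal_idx = rng.choice(config.n_snps, size=config.n_causal, replace=False)
        causal_idx = np.sort(causal_idx)
        beta = rng.standard_normal(config.n_causal)
        g_raw = dos[:, causal_idx] @ beta
        sd_raw = float(np.std(g_raw))
        target_sd = np.sqrt(config.h2) * config.pheno_sd
        scale = target_sd / sd_raw if sd_raw > 0 and target_sd > 0 else 0.0
        beta = beta * scale
    else:
        causal_idx = np.array([], dtype=int)
        beta = np.array([])

    if config.missing_rate > 0:
        mask = rng.random(dos.shape) < config.missing_rate
        dos[mask] = np.nan

    samples = [f"ctrl_{i:05d}" for i in range(config.n_controls)]
    geno = GenotypeMatrix(dos, samples, snps)
    g = np.nan_to_num(dos[:, causal_idx]) @ beta if len(causal_idx) else np.zeros(config.n_controls)
    model = TrueModel(
        causal_snp_ids=list(snps["id"].iloc[causal_idx]),
        causal_effects=beta,
        covariate_effects=dict(config.covariate_effects),
        intercept=0.0,  # filled by simulate_phenotypes
        genetic_sd=float(np.std(g)),
        allele_freqs=freqs,
        latent_rho=rho,
    )
    return geno, model


# --------------------------------------------------------------------- #
# phenotypes
# --------------------------------------------------------------------- #
def _draw_covariates(n: int, marginals: dict, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(
        rng.normal(marginals["age_mean"], marginals["age_sd"], n), *marginals["age_range"]
    )
    sex = (rng.random(n) < marginals["female"]).astype(int)
    smoking = rng.choice(3, size=n, p=np.asarray(marginals["smoking"]) / sum(marginals["smoking"]))
    atopy = (rng.random(n) < marginals["atopy"]).astype(int)
    return pd.DataFrame({"age": age, "sex": sex, "smoking": smoking, "atopy": atopy})


def true_genetic_values(genotypes: GenotypeMatrix, model: TrueModel) -> np.ndarray:
    """Sum of causal effects times dosage (missing treated as 0 copies)."""
    sub = genotypes.take_snps(np.asarray(model.causal_snp_ids, dtype=object))
    return np.nan_to_num(sub.dosages) @ np.asarray(model.causal_effects)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, model: TrueModel, config: SimConfig
) -> pd.DataFrame:
    """Control cohort table: log-IgE from the additive model plus covariates.

    log-IgE = intercept + genetic value + covariate terms + Gaussian noise,
    with noise SD sqrt(1 - h2) * pheno_sd so the genetic variance fraction
    (given covariates) is ~h2.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = genotypes.n_samples
    cov = _draw_covariates(n, CONTROL_MARGINALS, rng)
    g = true_genetic_values(genotypes, model)
    ce = model.covariate_effects
    cov_term = (
        ce.get("sex", 0.0) * cov["sex"].values
        + ce.get("smoking", 0.0) * cov["smoking"].values
        + ce.get("atopy", 0.0) * cov["atopy"].values
        + ce.get("age", 0.0) * (cov["age"].values - CONTROL_MARGINALS["age_mean"])
    )
    noise = rng.normal(0.0, np.sqrt(max(1.0 - config.h2, 0.0)) * config.pheno_sd, n)
    intercept = config.pheno_mean - float(np.mean(g)) - float(np.mean(cov_term))
    model.intercept = intercept
    log_ige = intercept + g + cov_term + noise
    out = pd.DataFrame({"sample": genotypes.samples, "log_ige": log_ige})
    out = pd.concat([out, cov], axis=1)
    out["asthma"] = 0
    out["onset_age"] = np.nan
    out["pfev1"] = rng.normal(CONTROL_MARGINALS["pfev1_mean"], CONTROL_MARGINALS["pfev1_sd"], n)
    return out


# --------------------------------------------------------------------- #
# asthma case cohort with planted cluster structure
# --------------------------------------------------------------------- #
def draw_cluster_features(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw truth labels and the four cluster features from the case mixture."""
    comps = config.cluster_spec
    if not comps:
        raise ValueError("cluster_spec is empty")
    weights = np.array([c.weight for c in comps])
    labels = rng.choice(len(comps), size=config.n_cases, p=weights)
    feats = np.empty((config.n_cases, 4))
    for k, c in enumerate(comps):
        idx = np.flatnonzero(labels == k)
        feats[idx, 0] = rng.normal(c.prs_z_mean, c.prs_z_sd, len(idx))
        feats[idx, 1] = rng.normal(c.log_ige_mean, c.log_ige_sd, len(idx))
        feats[idx, 2] = np.clip(rng.normal(c.onset_mean, c.onset_sd, len(idx)), 0, None)
        feats[idx, 3] = np.clip(rng.normal(c.pfev1_mean, c.pfev1_sd, len(idx)), 20, 160)
    df = pd.DataFrame(feats, columns=["prs_burden_z", "log_ige", "onset_age", "pfev1"])
    return labels, df


def _tilt_causal_freqs(
    target_shift: np.ndarray, beta: np.ndarray, p0: np.ndarray
) -> np.ndarray:
    """Per-individual exponentially tilted causal allele frequencies.

    Solves (bisection, vectorized over individuals) for the tilt t_i such that
    the expected genetic value shift sum_j 2 beta_j (p'_ij - p_j) hits the
    target, with p'_ij = p_j e^{t beta_j} / (p_j e^{t beta_j} + 1 - p_j).
    """

    def shift(t):
        w = p0 * np.exp(np.outer(t, beta))
        p1 = w / (w + (1.0 - p0))
        return 2.0 * (p1 - p0) @ beta, p1

    lo = np.full(len(target_shift), -60.0)
    hi = np.full(len(target_shift), 60.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        s, _ = shift(mid)
        too_low = s < target_shift
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    _, p1 = shift(0.5 * (lo + hi))
    return p1


def simulate_asthma_cohort(
    config: SimConfig, model: TrueModel
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Case genotypes and cohort table with planted 4-cluster structure.

    Each case is drawn from one mixture component over (genetic IgE burden,
    log IgE, onset age, pFEV1). Causal genotypes are frequency-tilted so the
    case's expected true genetic value matches its drawn burden; non-causal
    SNPs follow the reference panel's LD model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    snps, block_of = _snp_table(config)
    labels, feats = draw_cluster_features(config, rng)

    dos = _draw_genotypes(config.n_cases, model.allele_freqs, block_of, model.latent_rho, rng)
    if len(model.causal_snp_ids):
        cidx = snps.set_index("id").index.get_indexer(model.causal_snp_ids)
        beta = np.asarray(model.causal_effects)
        p0 = model.allele_freqs[cidx]
        target = feats["prs_burden_z"].values * model.genetic_sd
        p_tilt = _tilt_causal_freqs(target, beta, p0)
        dos[:, cidx] = rng.binomial(2, p_tilt).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dos.shape) < config.missing_rate
        dos[mask] = np.nan

    samples = [f"case_{i:05d}" for i in range(config.n_cases)]
    geno = GenotypeMatrix(dos, samples, snps)
    cov = _draw_covariates(config.n_cases, CASE_MARGINALS, rng)
    cov["age"] = np.maximum(cov["age"].values, feats["onset_age"].values)
    table = pd.DataFrame({"sample": samples, "log_ige": feats["log_ige"].values})
    table = pd.concat([table, cov], axis=1)
    table["asthma"] = 1
    table["onset_age"] = feats["onset_age"].values
    table["pfev1"] = feats["pfev1"].values
    table["cluster_truth"] = labels + 1
    table["prs_burden_z"] = feats["prs_burden_z"].values
    model.cluster_labels_truth = labels + 1
    return geno, table


# --------------------------------------------------------------------- #
# QC artifact injection
# --------------------------------------------------------------------- #
def inject_artifacts(genotypes: GenotypeMatrix, spec: dict, seed: int = 0) -> GenotypeMatrix:
    """Inject QC-visible artifacts; ``spec`` keys (all optional):

    - ``high_missing``: {"ids": [...], "rate": float} — raise per-sample
      missingness to ~rate for the listed samples.
    - ``duplicates``: [(source_id, new_id), ...] — append exact copies.
    - ``parent_offspring``: [(parent_id, new_id), ...] — append children with
      one Mendelian gamete from the parent, one from the population.
    - ``het_inflated``: {"ids": [...], "extra": float} — convert the given
      fraction of homozygous calls to heterozygous.

    An empty spec returns the input unchanged.
    """
    if not spec:
        return genotypes
    rng = np.random.default_rng(seed)
    known = set(genotypes.samples)
    for key in ("duplicates", "parent_offspring"):
        for src, _new in spec.get(key, []):
            if src not in known:
                raise ValueError(f"{key}: unknown sample id {src!r}")
    n_new = len(spec.get("duplicates", [])) + len(spec.get("parent_offspring", []))
    if n_new > genotypes.n_samples:
        raise ValueError("requested artifact count exceeds cohort size")

    dos = genotypes.dosages.copy()
    samples = list(genotypes.samples)

    hm = spec.get("high_missing")
    if hm:
        idx = genotypes.sample_index(hm["ids"])
        rate = float(hm["rate"])
        for i in idx:
            mask = rng.random(dos.shape[1]) < rate
            dos[i, mask] = np.nan

    hi = spec.get("het_inflated")
    if hi:
        idx = genotypes.sample_index(hi["ids"])
        extra = float(hi.get("extra", 0.3))
        for i in idx:
            hom = np.flatnonzero((dos[i] == 0) | (dos[i] == 2))
            flip = hom[rng.random(len(hom)) < extra]
            dos[i, flip] = 1.0

    new_rows, p = [], genotypes.effect_allele_freq()
    for src, new_id in spec.get("duplicates", []):
        new_rows.append((new_id, dos[samples.index(src)].copy()))
    for src, new_id in spec.get("parent_offspring", []):
        parent = dos[samples.index(src)]
        gamete = np.where(
            np.isnan(parent), np.nan,
            np.where(parent == 0, 0.0, np.where(parent == 2, 1.0, (rng.random(len(parent)) < 0.5).astype(float))),
        )
        pop_hap = (rng.random(len(parent)) < np.nan_to_num(p, nan=0.5)).astype(float)
        child = gamete + pop_hap
        new_rows.append((new_id, child))
    if new_rows:
        dos = np.vstack([dos] + [r[1][None, :] for r in new_rows])
        samples = samples + [r[0] for r in new_rows]
    return GenotypeMatrix(dos, samples, genotypes.snps.copy())
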