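"""Clumping + thresholding polygenic risk scores for total IgE.

The score for individual j is the mean weighted dosage

    PRS_j = (1 / M_j) * sum_i S_i * G_ij

where S_i is the per-effect-allele summary statistic of SNP i, G_ij the
effect-allele dosage (0/1/2), and M_j the number of SNPs with a non-missing
genotype in individual j. SNP sets come from greedy LD clumping followed by
p-value thresholding, with the threshold chosen to maximize the incremental
R2 of the score over a covariate-only regression in a target sample.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, pairwise_r2
from .assoc import build_design

logger = logging.getLogger(__name__)

DEFAULT_R2_MAX = 0.1
DEFAULT_WINDOW_KB = 250.0
DEFAULT_GRID = (5e-8, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)


@dataclass
class PrsModel:
    """A fitted per-fold PRS: SNP ids, effect alleles, weights, threshold."""

    snps: list
    effect_alleles: list
    weights: np.ndarray
    p_threshold: float
    clump_r2: float = DEFAULT_R2_MAX
    clump_window_kb: float = DEFAULT_WINDOW_KB
    fold: int | None = None
    r2_trace: list = field(default_factory=list)  # (threshold, incremental R2)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["weights"] = np.asarray(self.weights).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PrsModel":
        with open(path) as fh:
            d = json.load(fh)
        d["weights"] = np.asarray(d["weights"], dtype=float)
        return cls(**d)


# --------------------------------------------------------------------- #
# clumping
# --------------------------------------------------------------------- #
def ld_clump(
    stats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_max: float = DEFAULT_R2_MAX,
    window_kb: float = DEFAULT_WINDOW_KB,
    p_index_max: float = 1.0,
) -> list:
    """Greedy LD clumping; returns retained index-SNP ids in selection order.

    SNPs with p <= ``p_index_max`` are visited in ascending p (ties broken by
    position, then id); each retained index SNP removes candidates on the same
    chromosome within ``window_kb`` kilobases whose dosage r2 with it is >=
    ``r2_max``. The result is independent of the input row order.
    """
    snp_pos = {s: i for i, s in enumerate(genotypes.snps["id"])}
    df = stats[stats["p"] <= p_index_max].copy()
    df = df[df["snp"].isin(snp_pos)].dropna(subset=["p"])
    df = df.sort_values(["p", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(dtype=float)
    ids = df["snp"].to_numpy()
    col = np.array([snp_pos[s] for s in ids], dtype=int)

    alive = np.ones(len(df), dtype=bool)
    kept = []
    window = window_kb * 1000.0
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept.append(ids[i])
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        near[i] = False
        cand = np.flatnonzero(near)
        if len(cand):
            r2 = pairwise_r2(genotypes.dosages, col[i], col[cand])
            alive[cand[r2 >= r2_max]] = False
        alive[i] = False
    return kept


# --------------------------------------------------------------------- #
# scoring
# --------------------------------------------------------------------- #
def score_prs(genotypes: GenotypeMatrix, model: PrsModel) -> pd.DataFrame:
    """Score samples; returns DataFrame (sample, prs, m).

    Model SNPs absent from the genotypes are dropped with a warning. Effect
    alleles are reconciled: when the model's effect allele matches the
    genotype's other allele, the dosage enters as 2 - G (equivalently the
    strand-consistent allele flip). Samples with no non-missing scored SNP
    get a NaN score with m = 0.
    """
    geno_idx = {s: i for i, s in enumerate(genotypes.snps["id"])}
    cols, weights, flip = [], [], []
    dropped = 0
    for snp, ea, w in zip(model.snps, model.effect_alleles, model.weights):
        j = geno_idx.get(snp)
        if j is None:
            dropped += 1
            continue
        row = genotypes.snps.iloc[j]
        if row["effect_allele"] == ea:
            flip.append(False)
        elif row["other_allele"] == ea:
            flip.append(True)
        else:
            dropped += 1
            continue
        cols.append(j)
        weights.append(w)
    if dropped:
        warnings.warn(f"score_prs: dropped {dropped} model SNPs absent or allele-mismatched")
    if not cols:
        raise ValueError("no model SNPs available in the genotype matrix")
    G = genotypes.dosages[:, cols].copy()
    flip = np.asarray(flip)
    if flip.any():
        G[:, flip] = 2.0 - G[:, flip]
    S = np.asarray(weights)
    contrib = G * S  # NaN propagates for missing
    m = np.sum(~np.isnan(G), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        total = np.nansum(contrib, axis=1)
        prs = np.where(m > 0, total / np.maximum(m, 1), np.nan)
    if (m == 0).any():
        warnings.warn(f"score_prs: {int((m == 0).sum())} samples with no scored SNPs -> NaN")
    return pd.DataFrame({"sample": genotypes.samples, "prs": prs, "m": m})


def _incremental_r2(y: np.ndarray, prs: np.ndarray, W: np.ndarray) -> float:
    """R2 gain of adding the PRS to the covariate-only least-squares fit."""
    ok = ~np.isnan(prs)
    y, prs, W = y[ok], prs[ok], W[ok]
    Q, _ = np.linalg.qr(W)
    ey = y - Q @ (Q.T @ y)
    ex = prs - Q @ (Q.T @ prs)
    syy = float(ey @ ey)
    sxx = float(ex @ ex)
    if syy <= 0 or sxx <= 0:
        return 0.0
    return float((ex @ ey) ** 2 / (sxx * syy))


def optimize_threshold(
    stats_clumped: pd.DataFrame,
    target_genotypes: GenotypeMatrix,
    target_phenotype,
    covariates: pd.DataFrame | None = None,
    grid=DEFAULT_GRID,
    clump_r2: float = DEFAULT_R2_MAX,
    clump_window_kb: float = DEFAULT_WINDOW_KB,
    fold: int | None = None,
) -> PrsModel:
    """Pick the p-value threshold maximizing incremental R2 in the target.

    ``stats_clumped`` must already be restricted to clump-independent SNPs.
    For each threshold in ``grid`` the target samples are scored with the
    SNPs at p <= threshold and the phenotype is regressed on PRS +
    covariates; the returned model carries the winning SNP set and the full
    (threshold, incremental R2) trace.
    """
    grid = sorted(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    y = np.asarray(target_phenotype, dtype=float)
    W, _ = build_design(covariates, target_genotypes.n_samples)
    df = stats_clumped.dropna(subset=["p", "beta"]).sort_values("p", kind="mergesort")
    trace, best = [], None
    for thr in grid:
        sub = df[df["p"] <= thr]
        if sub.empty:
            logger.info("threshold %g retains no SNPs; skipped", thr)
            continue
        model = PrsModel(
            snps=list(sub["snp"]),
            effect_alleles=list(sub["effect_allele"]),
            weights=sub["beta"].to_numpy(),
            p_threshold=thr,
            clump_r2=clump_r2,
            clump_window_kb=clump_window_kb,
            fold=fold,
        )
        prs = score_prs(target_genotypes, model)["prs"].to_numpy()
        r2 = _incremental_r2(y, prs, W)
        trace.append((thr, r2))
        if best is None or r2 > best[0]:
            best = (r2, model)
    if best is None:
        raise ValueError("every threshold retained zero SNPs")
    best[1].r2_trace = trace
    return best[1]
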