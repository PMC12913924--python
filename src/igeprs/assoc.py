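"""Genotype PCA, per-SNP association scans, and lead-SNP selection.

Summary statistics are plain DataFrames with one row per SNP and columns
``snp, chrom, pos, effect_allele, other_allele, beta, se, p, n`` (the
on-disk TSV uses the same columns). Quantitative scans are covariate-adjusted
least squares on the effect-allele dosage; the case-control scan is the
covariate-free 1-df allelic chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

STAT_COLUMNS = ["snp", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p", "n"]
P_FLOOR = 1e-300


# --------------------------------------------------------------------- #
# PCA
# --------------------------------------------------------------------- #
@dataclass
class PcaModel:
    """Genotype PCA with stored standardization, projectable onto new samples."""

    means: np.ndarray  # 2 * p_hat per SNP
    scales: np.ndarray  # sqrt(2 p (1-p)); 1.0 for skipped constant SNPs
    loadings: np.ndarray  # SNPs x k
    scores: pd.DataFrame  # samples x PC1..PCk
    snp_ids: np.ndarray

    def project(self, genotypes: GenotypeMatrix) -> pd.DataFrame:
        """Project new samples onto the fitted components (no refit)."""
        sub = genotypes.take_snps(self.snp_ids)
        X = (sub.dosages - self.means) / self.scales
        X = np.nan_to_num(X, nan=0.0)
        scores = X @ self.loadings
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(scores, index=sub.samples, columns=cols)


def genotype_pca(genotypes: GenotypeMatrix, k: int = 5, seed: int = 0) -> PcaModel:
    """Top-k PCA of standardized dosages.

    SNPs are centered at 2*p_hat and scaled by sqrt(2 p (1-p)); missing calls
    are set to 0 after centering. Constant SNPs are skipped (count logged).
    """
    if k < 0 or (k > 0 and k >= min(genotypes.n_samples, genotypes.n_snps)):
        raise ValueError("k must satisfy 0 <= k < min(n_samples, n_snps)")
    p = genotypes.effect_allele_freq()
    ok = np.isfinite(p) & (p > 0) & (p < 1)
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("genotype_pca: skipped %d constant/empty SNPs", n_skip)
    sub = genotypes.take_snps(ok)
    p = p[ok]
    means = 2.0 * p
    scales = np.sqrt(2.0 * p * (1.0 - p))
    X = np.nan_to_num((sub.dosages - means) / scales, nan=0.0)
    X = X - X.mean(axis=0)  # exact column centering after missing-fill

    if k == 0:
        scores = pd.DataFrame(index=sub.samples)
        V = np.zeros((sub.n_snps, 0))
    elif min(X.shape) <= 200:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
        V = Vt.T
        scores = pd.DataFrame(U * s, index=sub.samples,
                              columns=[f"PC{i + 1}" for i in range(k)])
    else:
        from sklearn.utils.extmath import randomized_svd

        U, s, Vt = randomized_svd(X, n_components=k, n_iter=7, random_state=seed)
        V = Vt.T
        scores = pd.DataFrame(U * s, index=sub.samples,
                              columns=[f"PC{i + 1}" for i in range(k)])
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(V.shape[1]):
        imax = np.argmax(np.abs(V[:, j]))
        if V[imax, j] < 0:
            V[:, j] = -V[:, j]
            scores.iloc[:, j] = -scores.iloc[:, j]
    return PcaModel(means=means, scales=scales, loadings=V, scores=scores,
                    snp_ids=sub.snps["id"].to_numpy())


# --------------------------------------------------------------------- #
# covariate design helpers
# --------------------------------------------------------------------- #
def build_design(covariates: pd.DataFrame | None, n: int) -> tuple[np.ndarray, list]:
    """Intercept + covariate design matrix; rejects collinear columns by name."""
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1)), ["const"]
    C = covariates.to_numpy(dtype=float)
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match sample count")
    W = np.column_stack([np.ones(n), C])
    names = ["const"] + list(covariates.columns)
    bad = []
    for j in range(1, W.shape[1]):
        prev = W[:, :j]
        resid = W[:, j] - prev @ np.linalg.lstsq(prev, W[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(W[:, j])):
            bad.append(names[j])
    if bad:
        raise ValueError(f"collinear covariate columns: {bad}")
    return W, names


def _na_row(meta) -> dict:
    return dict(snp=meta.id, chrom=meta.chrom, pos=meta.pos,
                effect_allele=meta.effect_allele, other_allele=meta.other_allele,
                beta=np.nan, se=np.nan, p=np.nan, n=0)


# --------------------------------------------------------------------- #
# quantitative GWAS
# --------------------------------------------------------------------- #
def gwas_quantitative(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP least squares: phenotype ~ dosage + covariates.

    Fits on samples with a non-missing dosage (the phenotype and covariates
    must be complete). beta/SE/p come from the dosage coefficient with
    t-distributed inference on the residual degrees of freedom. SNPs with
    zero dosage variance or too few complete cases yield NA rows; perfect
    fits report p at the numerical floor.
    """
    y = np.asarray(phenotype, dtype=float)
    n = genotypes.n_samples
    if len(y) != n:
        raise ValueError("phenotype length does not match sample count")
    if np.isnan(y).any():
        raise ValueError("phenotype must be complete")
    W, _ = build_design(covariates, n)
    p_w = W.shape[1]
    D = genotypes.dosages

    Q, _ = np.linalg.qr(W)
    ey = y - Q @ (Q.T @ y)
    syy = float(ey @ ey)

    rows = []
    has_na = np.isnan(D).any(axis=0)
    # fast path: complete SNPs via Frisch-Waugh residualization
    comp = np.flatnonzero(~has_na)
    if len(comp):
        E = D[:, comp] - Q @ (Q.T @ D[:, comp])
        sxx = np.einsum("ij,ij->j", E, E)
        sxy = E.T @ ey
        df = n - p_w - 1
    for j, meta in enumerate(genotypes.snps.itertuples(index=False)):
        if not has_na[j]:
            k = np.searchsorted(comp, j)
            if sxx[k] <= 1e-12 or df < 1:
                rows.append(_na_row(meta))
                continue
            beta = sxy[k] / sxx[k]
            ssr = max(syy - beta * sxy[k], 0.0)
            rows.append(_t_row(meta, beta, ssr, sxx[k], df, n))
        else:
            ok = ~np.isnan(D[:, j])
            nj = int(ok.sum())
            if nj < p_w + 2:
                rows.append(_na_row(meta))
                continue
            Xj = np.column_stack([D[ok, j], W[ok]])
            if np.var(D[ok, j]) <= 1e-12:
                rows.append(_na_row(meta))
                continue
            coef, _, rank, _ = np.linalg.lstsq(Xj, y[ok], rcond=None)
            if rank < Xj.shape[1]:
                rows.append(_na_row(meta))
                continue
            resid = y[ok] - Xj @ coef
            dfj = nj - Xj.shape[1]
            XtX_inv = np.linalg.inv(Xj.T @ Xj)
            ssr = float(resid @ resid)
            sxx_j = 1.0 / XtX_inv[0, 0]
            rows.append(_t_row(meta, coef[0], ssr, sxx_j, dfj, nj))
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


def _t_row(meta, beta, ssr, sxx, df, n) -> dict:
    sigma2 = ssr / df
    if sigma2 <= 0:
        # perfect fit: degenerate, p at numerical floor
        return dict(snp=meta.id, chrom=meta.chrom, pos=meta.pos,
                    effect_allele=meta.effect_allele, other_allele=meta.other_allele,
                    beta=beta, se=0.0, p=P_FLOOR, n=n)
    se = np.sqrt(sigma2 / sxx)
    t = beta / se
    p = max(2.0 * sps.t.sf(abs(t), df), P_FLOOR)
    return dict(snp=meta.id, chrom=meta.chrom, pos=meta.pos,
                effect_allele=meta.effect_allele, other_allele=meta.other_allele,
                beta=beta, se=se, p=p, n=n)


# --------------------------------------------------------------------- #
# case-control GWAS
# --------------------------------------------------------------------- #
def gwas_casecontrol(genotypes: GenotypeMatrix, labels) -> pd.DataFrame:
    """Covariate-free 1-df allelic chi-square per SNP.

    beta is the log allelic odds ratio (effect vs other allele, cases vs
    controls) with SE = sqrt(sum of reciprocal cell counts); NaN when a cell
    is empty. Monomorphic SNPs yield NA rows.
    """
    lab = np.asarray(labels).astype(int)
    if lab.shape[0] != genotypes.n_samples:
        raise ValueError("labels length does not match sample count")
    if lab.sum() == 0 or lab.sum() == len(lab):
        raise ValueError("both case and control classes must be non-empty")
    D = genotypes.dosages
    rows = []
    case, ctrl = lab == 1, lab == 0
    for j, meta in enumerate(genotypes.snps.itertuples(index=False)):
        d = D[:, j]
        a_case = np.nansum(d[case])
        n_case = 2.0 * np.sum(~np.isnan(d[case]))
        a_ctrl = np.nansum(d[ctrl])
        n_ctrl = 2.0 * np.sum(~np.isnan(d[ctrl]))
        table = np.array([[a_case, n_case - a_case], [a_ctrl, n_ctrl - a_ctrl]])
        if table.sum() == 0 or min(table.sum(axis=0)) == 0:
            rows.append(_na_row(meta))
            continue
        exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = float(np.nansum((table - exp) ** 2 / exp))
        p = float(sps.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
        if (table > 0).all():
            beta = float(np.log(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0])))
            se = float(np.sqrt((1.0 / table).sum()))
        else:
            beta, se = np.nan, np.nan
        rows.append(dict(snp=meta.id, chrom=meta.chrom, pos=meta.pos,
                         effect_allele=meta.effect_allele, other_allele=meta.other_allele,
                         beta=beta, se=se, p=max(p, P_FLOOR),
                         n=int((n_case + n_ctrl) // 2)))
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


# --------------------------------------------------------------------- #
# lead SNPs
# --------------------------------------------------------------------- #
def select_lead_snps(
    stats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    p_max: float = 1e-5,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
) -> list:
    """Greedy lead-SNP selection at a suggestive threshold.

    Repeatedly takes the smallest-p SNP below ``p_max`` and excludes SNPs
    within ``window_kb`` on the same chromosome with r2 >= ``r2_max`` to it.
    """
    from .prs import ld_clump

    kept = ld_clump(stats[stats["p"] < p_max], genotypes,
                    r2_max=r2_max, window_kb=window_kb, p_index_max=1.0)
    return list(kept)


# --------------------------------------------------------------------- #
# IO
# --------------------------------------------------------------------- #
def write_summary_stats(stats: pd.DataFrame, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        stats.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
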