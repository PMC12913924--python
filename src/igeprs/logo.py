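"""Leave-one-group-out (LOGO) construction of the IgE polygenic risk score.

The reference (non-asthmatic) cohort is split into K random subgroups
(default 5). For each fold, a GWAS of log10 total IgE is run on the other
K-1 subgroups (adjusting for age, sex, smoking indicators, atopy, and
genetic principal components computed on those base samples), the summary
statistics are LD-clumped, the p-value threshold is optimized on the
held-out subgroup, and all samples are scored with the resulting model. The
K per-sample scores are then combined by fixed-effect inverse-variance
weighting,

    IgE_PRS = sum_i (PRS_i / SE_i^2) / sum_i (1 / SE_i^2),

where SE_i is the standard error of the PRS coefficient in the held-out
covariate-adjusted regression of fold i, and finally z-scored against the
reference cohort mean and SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .assoc import genotype_pca, gwas_quantitative, build_design
from .prs import (
    ld_clump,
    score_prs,
    optimize_threshold,
    DEFAULT_GRID,
    DEFAULT_R2_MAX,
    DEFAULT_WINDOW_KB,
)

logger = logging.getLogger(__name__)

MIN_FOLD_SIZE = 30
DEFAULT_COVARIATES = ("age", "sex", "smoking", "atopy")


@dataclass
class FoldAssignment:
    """Random partition of samples into K near-equal folds (1..K)."""

    folds: pd.Series  # index: sample id, values 1..K
    k: int
    seed: int

    def ids_in(self, fold: int) -> list:
        return list(self.folds.index[self.folds == fold])


def make_folds(sample_ids, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Uniform random partition into k folds with sizes differing by <= 1."""
    ids = list(sample_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError("k exceeds the number of samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assign = np.empty(len(ids), dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k), start=1):
        assign[chunk] = f
    return FoldAssignment(folds=pd.Series(assign, index=ids), k=k, seed=seed)


@dataclass
class ZScoreReference:
    """Mean/SD of the combined score in the reference (control) cohort."""

    mu: float
    sigma: float

    def z(self, x):
        return (np.asarray(x, dtype=float) - self.mu) / self.sigma


def meta_combine(fold_scores: pd.DataFrame, fold_ses) -> pd.Series:
    """Per-sample fixed-effect inverse-variance combination of fold scores."""
    ses = np.asarray(fold_ses, dtype=float)
    if not np.all(np.isfinite(ses)) or np.any(ses <= 0):
        raise ValueError("all fold SEs must be finite and positive")
    w = 1.0 / ses**2
    P = fold_scores.to_numpy(dtype=float)
    finite = np.isfinite(P)
    wmat = np.where(finite, w, 0.0)
    num = np.nansum(np.where(finite, P, 0.0) * wmat, axis=1)
    den = wmat.sum(axis=1)
    out = np.where(den > 0, num / den, np.nan)
    return pd.Series(out, index=fold_scores.index, name="ige_prs")


def zscore_reference(meta: pd.Series, reference_ids) -> tuple[pd.Series, ZScoreReference]:
    """Standardize against the reference samples' mean/SD (ddof=1)."""
    ref = meta.loc[list(reference_ids)]
    mu = float(ref.mean())
    sigma = float(ref.std(ddof=1))
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError("degenerate z-score reference (sigma <= 0)")
    zref = ZScoreReference(mu=mu, sigma=sigma)
    return pd.Series(zref.z(meta.to_numpy()), index=meta.index, name="ige_prs_z"), zref


def _encode_covariates(cohort: pd.DataFrame, columns) -> pd.DataFrame:
    """Covariate design columns; 3-category smoking becomes two indicators."""
    out = {}
    for c in columns:
        if c == "smoking":
            v = cohort[c].to_numpy()
            out["smoking_1"] = (v == 1).astype(float)
            out["smoking_2"] = (v == 2).astype(float)
        else:
            out[c] = cohort[c].to_numpy(dtype=float)
    return pd.DataFrame(out, index=cohort.index)


def _prs_coef_se(y: np.ndarray, prs: np.ndarray, W: np.ndarray) -> float:
    """SE of the PRS coefficient in y ~ PRS + covariates (least squares)."""
    ok = np.isfinite(prs)
    X = np.column_stack([prs[ok], W[ok]])
    yv = y[ok]
    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    df = len(yv) - X.shape[1]
    if df < 1:
        raise ValueError("not enough samples to estimate the PRS coefficient SE")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return float(np.sqrt(sigma2 * xtx_inv[0, 0]))


class IgePrsLogo:
    """Model object for the LOGO IgE PRS build on a reference cohort.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Post-QC reference genotypes.
    cohort : DataFrame
        One row per sample with a ``sample`` column matching the genotypes,
        the phenotype column and the covariate columns.
    phenotype : str
        Phenotype column (log10 total IgE by default).
    covariates : sequence of str
        Covariate columns; ``smoking`` is expanded to two indicators.
    k, n_pcs : int
        Number of folds and genetic principal components.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        cohort: pd.DataFrame,
        phenotype: str = "log_ige",
        covariates=DEFAULT_COVARIATES,
        k: int = 5,
        n_pcs: int = 5,
        clump_r2: float = DEFAULT_R2_MAX,
        clump_window_kb: float = DEFAULT_WINDOW_KB,
        grid=DEFAULT_GRID,
    ):
        cohort = cohort.set_index("sample") if "sample" in cohort.columns else cohort
        missing = [s for s in genotypes.samples if s not in cohort.index]
        if missing:
            raise ValueError(f"cohort table lacks {len(missing)} genotyped samples")
        self.genotypes = genotypes
        self.cohort = cohort.loc[list(genotypes.samples)]
        self.phenotype = phenotype
        self.covariate_cols = tuple(covariates)
        self.k = k
        self.n_pcs = n_pcs
        self.clump_r2 = clump_r2
        self.clump_window_kb = clump_window_kb
        self.grid = grid

    # ------------------------------------------------------------------ #
    def fit(self, seed: int = 0, folds: FoldAssignment | None = None) -> "LogoResults":
        ids = list(self.genotypes.samples)
        folds = folds or make_folds(ids, self.k, seed)
        sizes = folds.folds.value_counts()
        if (sizes < MIN_FOLD_SIZE).any():
            raise ValueError(f"fold smaller than {MIN_FOLD_SIZE} samples; SEs unstable")
        y = self.cohort[self.phenotype].to_numpy(dtype=float)
        base_cov = _encode_covariates(self.cohort, self.covariate_cols)

        fold_models, fold_ses, score_cols = [], [], {}
        heldout_r2 = []
        for f in range(1, folds.k + 1):
            held_mask = (folds.folds.loc[ids] == f).to_numpy()
            base_ids = [s for s, h in zip(ids, held_mask) if not h]
            held_ids = [s for s, h in zip(ids, held_mask) if h]
            g_base = self.genotypes.take_samples(base_ids)
            g_held = self.genotypes.take_samples(held_ids)

            if self.n_pcs > 0:
                pca = genotype_pca(g_base, self.n_pcs, seed=seed)
                pcs_base = pca.scores
                pcs_held = pca.project(g_held)
            else:
                pcs_base = pd.DataFrame(index=base_ids)
                pcs_held = pd.DataFrame(index=held_ids)

            cov_base = pd.concat(
                [base_cov.loc[base_ids].reset_index(drop=True),
                 pcs_base.reset_index(drop=True)], axis=1)
            cov_held = pd.concat(
                [base_cov.loc[held_ids].reset_index(drop=True),
                 pcs_held.reset_index(drop=True)], axis=1)

            stats = gwas_quantitative(g_base, y[~held_mask], cov_base)
            kept = ld_clump(stats, g_base, self.clump_r2, self.clump_window_kb)
            clumped = stats[stats["snp"].isin(set(kept))]
            model = optimize_threshold(
                clumped, g_held, y[held_mask], cov_held, grid=self.grid,
                clump_r2=self.clump_r2, clump_window_kb=self.clump_window_kb, fold=f)
            fold_models.append(model)
            heldout_r2.append(max(r2 for _, r2 in model.r2_trace))

            prs_all = score_prs(self.genotypes, model).set_index("sample")["prs"]
            score_cols[f"prs_{f}"] = prs_all
            W_held, _ = build_design(cov_held, len(held_ids))
            fold_ses.append(_prs_coef_se(y[held_mask], prs_all.loc[held_ids].to_numpy(), W_held))
            logger.info("fold %d: threshold %g, %d SNPs, SE %.4g",
                        f, model.p_threshold, len(model.snps), fold_ses[-1])

        fold_scores = pd.DataFrame(score_cols)
        combined = meta_combine(fold_scores, fold_ses)
        z, zref = zscore_reference(combined, ids)
        return LogoResults(
            model=self, folds=folds, fold_models=fold_models,
            fold_ses=np.asarray(fold_ses), fold_scores=fold_scores,
            combined=combined, z=z, zref=zref,
            heldout_incremental_r2=np.asarray(heldout_r2), seed=seed,
        )


@dataclass
class LogoResults:
    """Fitted LOGO PRS: per-fold models/SEs, combined scores, z reference."""

    model: IgePrsLogo
    folds: FoldAssignment
    fold_models: list
    fold_ses: np.ndarray
    fold_scores: pd.DataFrame
    combined: pd.Series
    z: pd.Series
    zref: ZScoreReference
    heldout_incremental_r2: np.ndarray
    seed: int

    @property
    def scores(self) -> pd.DataFrame:
        out = self.fold_scores.copy()
        out["ige_prs"] = self.combined
        out["ige_prs_z"] = self.z
        out.index.name = "sample"
        return out

    def apply_to_external(self, genotypes: GenotypeMatrix) -> pd.Series:
        """Score an external cohort with the reference fold models and scale."""
        return apply_to_external(self.fold_models, self.fold_ses, genotypes, self.zref)

    @property
    def heldout_scores(self) -> pd.Series:
        """Per-sample score from the sample's own held-out fold model only.

        Unlike the combined score (which mixes the four models whose GWAS
        included the sample), this score is fully out-of-sample and is the
        appropriate quantity for overfitting diagnostics.
        """
        ids = self.fold_scores.index
        f = self.folds.folds.loc[ids].to_numpy()
        cols = self.fold_scores.to_numpy()
        vals = cols[np.arange(len(ids)), f - 1]
        return pd.Series(vals, index=ids, name="prs_heldout")

    def heldout_r2(self) -> float:
        """Squared correlation of the fully held-out score with the phenotype."""
        y = self.model.cohort[self.model.phenotype].to_numpy(dtype=float)
        x = self.heldout_scores.to_numpy()
        ok = np.isfinite(x)
        r = np.corrcoef(x[ok], y[ok])[0, 1]
        return float(r * r)

    def phenotype_r2(self) -> float:
        """Squared Pearson correlation of the combined z with the phenotype."""
        y = self.model.cohort[self.model.phenotype].to_numpy(dtype=float)
        z = self.z.to_numpy()
        ok = np.isfinite(z)
        r = np.corrcoef(z[ok], y[ok])[0, 1]
        return float(r * r)

    def summary(self) -> str:
        lines = [
            "LOGO IgE PRS results",
            "====================",
            f"samples: {len(self.combined)}   folds: {self.folds.k}   seed: {self.seed}",
            f"reference z-score: mean {self.z.mean():.2f}, SD {self.z.std(ddof=1):.2f}",
            f"combined score vs phenotype R2: {self.phenotype_r2():.3f}",
            "",
            "fold  threshold  n_snps        SE  heldout_dR2",
        ]
        for i, m in enumerate(self.fold_models):
            lines.append(
                f"{i + 1:>4}  {m.p_threshold:>9.3g}  {len(m.snps):>6}  "
                f"{self.fold_ses[i]:>8.4f}  {self.heldout_incremental_r2[i]:>11.4f}"
            )
        return "\n".join(lines)


def apply_to_external(
    models: list, fold_ses, genotypes: GenotypeMatrix, zref: ZScoreReference
) -> pd.Series:
    """Score external samples with all fold models and standardize.

    Uses the reference build's fold SEs as weights and the reference mean/SD
    for the z transform. Warns when SNP coverage of any model drops below
    90%.
    """
    if not models:
        raise ValueError("empty model list")
    present = set(genotypes.snps["id"])
    cols = {}
    for m in models:
        cov = np.mean([s in present for s in m.snps]) if m.snps else 0.0
        if cov < 0.9:
            warnings.warn(
                f"fold {m.fold}: only {cov:.1%} of model SNPs present in external genotypes")
        cols[f"prs_{m.fold}"] = score_prs(genotypes, m).set_index("sample")["prs"]
    combined = meta_combine(pd.DataFrame(cols), fold_ses)
    return pd.Series(zref.z(combined.to_numpy()), index=combined.index, name="ige_prs_z")
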