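"""Group-comparison battery used in the cohort analyses.

Pearson chi-square (no continuity correction) for contingency tables,
Kruskal-Wallis with tie correction, Dunn z post-hoc tests with Bonferroni
adjustment, covariate-adjusted linear-regression group comparison, squared
Pearson correlation, and a Shapiro-Wilk/Levene gate that routes between
parametric and nonparametric comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


# --------------------------------------------------------------------- #
# chi-square
# --------------------------------------------------------------------- #
def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction; df = (r-1)(c-1); p from the upper chi-square
    tail. Zero row/column margins are rejected with the offending margin
    named.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    for i, r in enumerate(rows):
        if r == 0:
            raise ValueError(f"row {i} has zero margin")
    for j, c in enumerate(cols):
        if c == 0:
            raise ValueError(f"column {j} has zero margin")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


# --------------------------------------------------------------------- #
# rank-based tests
# --------------------------------------------------------------------- #
def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {i} is empty")
    values = np.concatenate(groups)
    if len(np.unique(values)) < 2:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass
class PairwiseComparisons:
    """Dunn post-hoc table: pair indices, z, raw and Bonferroni-adjusted p."""

    table: pd.DataFrame  # columns: group1, group2, z, p_raw, p_adjusted
    n_pairs: int


def dunn_bonferroni(groups) -> PairwiseComparisons:
    """Dunn z tests on mean ranks with tie-corrected pooled variance.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p, Bonferroni
    factor = number of pairs (adjusted p capped at 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {i} is empty")
    values = np.concatenate(groups)
    n_tot = len(values)
    ranks = sps.rankdata(values)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(groups))]
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    pairs = list(combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append((i, j, z, p_raw, min(1.0, p_raw * len(pairs))))
    return PairwiseComparisons(
        table=pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw", "p_adjusted"]),
        n_pairs=len(pairs),
    )


# --------------------------------------------------------------------- #
# regression and correlation
# --------------------------------------------------------------------- #
def adjusted_group_comparison(y, group, covariates: pd.DataFrame | None = None
                              ) -> tuple[float, float, float]:
    """Least-squares y ~ group + covariates; returns the group (beta, SE, p).

    Complete cases only (listwise deletion). Collinear designs raise.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=float)
    if covariates is not None and len(covariates):
        C = covariates.to_numpy(dtype=float)
        X = np.column_stack([g, C])
        names = ["group"] + list(covariates.columns)
    else:
        X = g[:, None]
        names = ["group"]
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, yv = sm.add_constant(X[ok], has_constant="add"), y[ok]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear design in columns {names}")
    fit = sm.OLS(yv, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def pearson_r2(x, y) -> tuple[float, float]:
    """Squared Pearson correlation with its t-test p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    r, p = sps.pearsonr(x, y)
    return float(r * r), float(p)


# --------------------------------------------------------------------- #
# parametric/nonparametric gate
# --------------------------------------------------------------------- #
@dataclass
class GateDecision:
    decision: str  # "parametric" | "nonparametric"
    reason: str
    shapiro_ps: list
    levene_p: float | None


def normality_variance_gate(groups, alpha: float = 0.05) -> GateDecision:
    """Route to parametric tests only when every group passes Shapiro-Wilk
    and Levene's test (mean-centered) does not reject; otherwise
    nonparametric. Groups smaller than 3 force the nonparametric route."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 3 for g in groups):
        return GateDecision("nonparametric", "group too small for normality test", [], None)
    shapiro_ps = [float(sps.shapiro(g).pvalue) for g in groups]
    if any(p < alpha for p in shapiro_ps):
        return GateDecision("nonparametric", "normality rejected", shapiro_ps, None)
    lev_p = float(sps.levene(*groups, center="mean").pvalue)
    if lev_p < alpha:
        return GateDecision("nonparametric", "variance homogeneity rejected", shapiro_ps, lev_p)
    return GateDecision("parametric", "assumptions satisfied", shapiro_ps, lev_p)
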