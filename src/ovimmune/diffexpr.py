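"""Per-gene case-vs-control differential expression.

A two-group linear model per gene with empirical-Bayes variance moderation:
per-gene sample variances are shrunk toward a common prior variance s0^2
with prior degrees of freedom d0, both estimated by the method of moments
from the distribution of log sample variances (Fisher's z for variances).
The moderated t statistic uses d0 + d degrees of freedom, where d is the
per-gene residual degrees of freedom.  Multiple testing is controlled by
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .harmonize import ExpressionMatrix

__all__ = ["fit_linear_de", "bh_fdr", "select_de"]

DEFAULT_LFC_THRESHOLD = 1.1
DEFAULT_P_THRESHOLD = 0.001


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Models log sample variances as log s0^2 plus a scaled log-F variate;
    matches the first two moments of e = log(s2) - digamma(d/2) + log(d/2).
    Returns ``d0 = inf`` when the observed spread is no larger than the
    chi-square sampling spread (complete shrinkage to s0^2).
    """
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    excess = e_var - float(polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(e_mean)
    return d0, float(s0_2)


def fit_linear_de(
    matrix: ExpressionMatrix,
    cohort_covariate: bool = False,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Moderated two-group differential expression for every gene.

    Returns a DataFrame indexed by gene with columns ``logFC`` (log2 case
    minus control mean), ``s2`` (raw pooled variance), ``t`` (moderated
    statistic), ``df`` (total degrees of freedom), ``p`` and ``q`` (BH).

    When ``cohort_covariate`` is set, the per-gene model additionally
    adjusts for cohort membership via fixed effects; the reported logFC is
    then the phenotype coefficient of that model.  ``prior`` fixes
    (d0, s0^2) instead of estimating them; d0 -> 0 reproduces the ordinary
    two-sample t-test.
    """
    case = matrix.phenotype_mask("case")
    control = matrix.phenotype_mask("control")
    n1, n2 = int(case.sum()), int(control.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each phenotype group needs at least two samples")
    x = matrix.values.to_numpy(dtype=float)

    if cohort_covariate:
        logfc, s2, df, var_scale = _fit_with_cohort(matrix, x, case)
    else:
        m1 = x[:, case].mean(axis=1)
        m2 = x[:, control].mean(axis=1)
        logfc = m1 - m2
        ss1 = x[:, case].var(axis=1, ddof=1) * (n1 - 1)
        ss2 = x[:, control].var(axis=1, ddof=1) * (n2 - 1)
        df = float(n1 + n2 - 2)
        s2 = (ss1 + ss2) / df
        var_scale = 1.0 / n1 + 1.0 / n2

    zero = s2 <= 0
    if zero.any():
        positive = s2[~zero]
        if positive.size == 0:
            raise ValueError("all genes have zero variance")
        s2 = s2.copy()
        s2[zero] = positive.min()
        warnings.warn(
            f"{int(zero.sum())} zero-variance genes assigned the smallest "
            "positive sample variance",
            stacklevel=2,
        )

    d0, s0_2 = estimate_prior(s2, df) if prior is None else prior
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        total_df = 1e6  # effectively normal reference
    else:
        s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
        total_df = d0 + df

    from scipy.stats import t as t_dist

    t_stat = logfc / np.sqrt(s2_tilde * var_scale)
    p = 2.0 * t_dist.sf(np.abs(t_stat), total_df)
    q = bh_fdr(p)
    return pd.DataFrame(
        {"logFC": logfc, "s2": s2, "t": t_stat, "df": total_df, "p": p, "q": q},
        index=matrix.genes,
    )


def _fit_with_cohort(
    matrix: ExpressionMatrix, x: np.ndarray, case: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-gene OLS with phenotype plus cohort fixed effects (shared design)."""
    cohorts = pd.get_dummies(matrix.metadata["cohort"], drop_first=True)
    design = np.column_stack(
        [np.ones(x.shape[1]), case.astype(float), cohorts.to_numpy(dtype=float)]
    )
    q_, r_ = np.linalg.qr(design)
    coef = np.linalg.solve(r_, q_.T @ x.T)  # p x genes
    resid = x.T - design @ coef
    df = float(x.shape[1] - design.shape[1])
    if df < 1:
        raise ValueError("cohort-adjusted model has no residual degrees of freedom")
    s2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    return coef[1], s2, df, float(xtx_inv[1, 1])


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de(
    table: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    use_q: bool = False,
) -> list[str]:
    """Genes with |logFC| strictly above and p strictly below threshold.

    Strict inequalities on both sides; the raw p column is used by default.
    Returns gene ids ordered by ascending p (ties by descending |logFC|).
    """
    if lfc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if table.empty:
        return []
    pcol = "q" if use_q else "p"
    hits = table[(table["logFC"].abs() > lfc_threshold) & (table[pcol] < p_threshold)]
    hits = hits.sort_values([pcol, "logFC"], key=lambda s: s if s.name == pcol else -s.abs())
    return list(hits.index)
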