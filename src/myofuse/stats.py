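"""Mixed-model comparison layer for aggregated classification accuracies.

Accuracy observations y_ij (participant i, factor level j — typically
sensing modality) are modelled with a random-intercept linear mixed
model,

    y_ij = beta_j + u_i + e_ij,  u_i ~ N(0, s2_u),  e_ij ~ N(0, s2_e),

fit by restricted maximum likelihood (REML).  The implementation profiles
the variance ratio theta = s2_u / s2_e: for any candidate theta the fixed
effects have a closed-form GLS solution (the per-subject covariance
I + theta J inverts analytically), so REML reduces to a deterministic 1-D
bounded minimisation over log(theta).  With a cell-means design matrix
the fixed-effect coefficients are the estimated marginal means (EMMs)
directly, and under a balanced design they equal the raw level means.

Pairwise level contrasts use the GLS coefficient covariance with a normal
(z) reference distribution, and the Benjamini-Hochberg step-up procedure
controls the false discovery rate across the pairs of one model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LMEFit",
    "fit_random_intercept_lme",
    "reml_neg2_restricted_loglik",
    "pairwise_emm_contrasts",
    "bh_fdr",
]


@dataclass
class LMEFit:
    levels: list
    emm: np.ndarray  # (K,) estimated marginal means (cell means)
    emm_se: np.ndarray  # (K,)
    coef_cov: np.ndarray  # (K, K) covariance of the EMMs
    sigma_u: float  # random-intercept SD
    sigma_e: float  # residual SD
    var_ratio: float  # sigma_u^2 / sigma_e^2
    n_subjects: int
    n_observations: int
    reml_criterion: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level": self.levels, "emm": self.emm, "se": self.emm_se}
        )


def _group_blocks(df, value_col, level_col, subject_col, levels):
    """Per-subject design blocks (X_i, y_i) with cell-means coding."""
    level_index = {lev: i for i, lev in enumerate(levels)}
    blocks = []
    for _, grp in df.groupby(subject_col, sort=True):
        Xi = np.zeros((len(grp), len(levels)))
        for r, lev in enumerate(grp[level_col]):
            Xi[r, level_index[lev]] = 1.0
        blocks.append((Xi, grp[value_col].to_numpy(dtype=float)))
    return blocks


def _gls_pieces(blocks, theta):
    """Accumulate GLS quantities under V_i = I + theta * J.

    V_i^-1 = I - theta/(1 + n_i theta) J by Sherman-Morrison, so every
    product reduces to row sums — no matrix inversions needed.
    """
    k = blocks[0][0].shape[1]
    A = np.zeros((k, k))
    b = np.zeros(k)
    logdet_v = 0.0
    for Xi, yi in blocks:
        ni = Xi.shape[0]
        c = theta / (1.0 + ni * theta)
        xs = Xi.sum(axis=0)
        A += Xi.T @ Xi - c * np.outer(xs, xs)
        b += Xi.T @ yi - c * xs * yi.sum()
        logdet_v += np.log1p(ni * theta)
    return A, b, logdet_v


def _weighted_rss(blocks, beta, theta):
    rss = 0.0
    for Xi, yi in blocks:
        ri = yi - Xi @ beta
        ni = ri.size
        c = theta / (1.0 + ni * theta)
        rss += ri @ ri - c * ri.sum() ** 2
    return rss


def reml_neg2_restricted_loglik(blocks, theta) -> float:
    """-2 restricted log-likelihood profiled over beta and sigma_e (+const).

    Exposed so a brute-force grid search can serve as an independent
    check of the optimiser.
    """
    A, b, logdet_v = _gls_pieces(blocks, theta)
    beta = np.linalg.solve(A, b)
    rss = _weighted_rss(blocks, beta, theta)
    n = sum(yi.size for _, yi in blocks)
    p = A.shape[0]
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return (n - p) * np.log(rss / (n - p)) + logdet_v + logdet_a


def fit_random_intercept_lme(
    records: pd.DataFrame,
    value_col: str = "accuracy_pct",
    level_col: str = "modality",
    subject_col: str = "participant_id",
    transform: str = "none",
) -> LMEFit:
    """REML fit of the random-intercept model to a tidy record table.

    Requires at least 2 factor levels, at least 3 subjects, and every
    subject observed at every level.  ``transform='rank'`` replaces the
    response by its ranks (a pragmatic option when accuracies are far
    from normal); the default fits the raw values.
    """
    for col in (value_col, level_col, subject_col):
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
    df = records[[subject_col, level_col, value_col]].copy()
    if transform == "rank":
        df[value_col] = sps.rankdata(df[value_col])
    elif transform != "none":
        raise ValueError("transform must be 'none' or 'rank'")

    levels = sorted(df[level_col].unique().tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 factor levels")
    subjects = df[subject_col].unique()
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    cells = df.groupby([subject_col, level_col]).size().unstack(fill_value=0)
    if (cells.reindex(columns=levels).to_numpy() == 0).any():
        raise ValueError("every subject must be observed at every level")

    blocks = _group_blocks(df, value_col, level_col, subject_col, levels)

    res = optimize.minimize_scalar(
        lambda log_theta: reml_neg2_restricted_loglik(blocks, np.exp(log_theta)),
        bounds=(-30.0, 30.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    theta = float(np.exp(res.x))
    # the boundary theta -> 0 (no subject variance) may beat the interior
    if reml_neg2_restricted_loglik(blocks, 0.0) < res.fun:
        theta = 0.0

    A, b, _ = _gls_pieces(blocks, theta)
    beta = np.linalg.solve(A, b)
    n = sum(yi.size for _, yi in blocks)
    p = len(levels)
    sigma2_e = _weighted_rss(blocks, beta, theta) / (n - p)
    coef_cov = sigma2_e * np.linalg.inv(A)

    return LMEFit(
        levels=levels,
        emm=beta,
        emm_se=np.sqrt(np.diag(coef_cov)),
        coef_cov=coef_cov,
        sigma_u=float(np.sqrt(theta * sigma2_e)),
        sigma_e=float(np.sqrt(sigma2_e)),
        var_ratio=theta,
        n_subjects=len(subjects),
        n_observations=n,
        reml_criterion=float(reml_neg2_restricted_loglik(blocks, theta)),
    )


def pairwise_emm_contrasts(fit: LMEFit, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise EMM differences with BH-adjusted z-test p-values.

    One row per unordered level pair: estimate (level_a - level_b),
    standard error from the GLS coefficient covariance, raw normal
    p-value, BH-adjusted p-value, and a significance flag at ``alpha``.
    """
    if len(fit.levels) < 2:
        raise ValueError("need at least 2 levels for contrasts")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for i, j in itertools.combinations(range(len(fit.levels)), 2):
        est = fit.emm[i] - fit.emm[j]
        se = np.sqrt(fit.coef_cov[i, i] + fit.coef_cov[j, j] - 2 * fit.coef_cov[i, j])
        z = est / se if se > 0 else np.inf * np.sign(est)
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "level_a": fit.levels[i],
                "level_b": fit.levels[j],
                "estimate": est,
                "se": se,
                "z": z,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ) over the sorted
    p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj
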