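"""Shared statistical machinery for cohort group comparisons.

Covariate-adjusted GLM contrasts, subject-label permutation nulls, the pooled
two-sample t from printed summaries, Hedges' small-sample-corrected effect
size, and covariate-adjusted Pearson/Spearman association.

Design convention: the design matrix uses cell-means coding for the two
groups (one indicator column per group, no intercept) followed by covariates,
which are mean-centered so that group-indicator coefficients estimate
covariate-adjusted group means.  A contrast ``[1, -1, 0, 0]`` then tests the
adjusted control-minus-TBI difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DesignMatrix",
    "EffectReport",
    "design_from_cohort",
    "glm_contrast_ttest",
    "permutation_pvalue",
    "pooled_two_sample_t",
    "hedges_g",
    "adjusted_association",
    "group_comparison_table",
    "CONTRAST_CONTROL",
    "CONTRAST_TBI",
    "CONTRAST_CONTROL_MINUS_TBI",
    "CONTRAST_TBI_MINUS_CONTROL",
]

CONTRAST_CONTROL = (1.0, 0.0)
CONTRAST_TBI = (0.0, 1.0)
CONTRAST_CONTROL_MINUS_TBI = (1.0, -1.0)
CONTRAST_TBI_MINUS_CONTROL = (-1.0, 1.0)


@dataclass
class DesignMatrix:
    """Subjects x predictors design with named columns.

    The first two columns are the control/TBI indicators; remaining columns
    are centered covariates.
    """

    matrix: np.ndarray
    columns: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if len(self.columns) != self.matrix.shape[1]:
            raise ValueError("column names must match design width")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    def with_groups(self, is_control: np.ndarray) -> "DesignMatrix":
        """Same covariates, group indicators replaced (used by permutations)."""
        x = self.matrix.copy()
        x[:, 0] = is_control.astype(float)
        x[:, 1] = 1.0 - is_control.astype(float)
        return DesignMatrix(x, self.columns)

    def full_contrast(self, group_contrast) -> np.ndarray:
        c = np.zeros(self.matrix.shape[1])
        c[: len(group_contrast)] = group_contrast
        return c


def design_from_cohort(
    cohort: pd.DataFrame, covariates=("age", "fd_mean")
) -> DesignMatrix:
    """Build a two-group design from a cohort table.

    The table needs a ``group`` column with values 'control'/'tbi' plus one
    column per requested covariate.  Covariates are mean-centered.
    """
    groups = cohort["group"].to_numpy()
    bad = set(groups) - {"control", "tbi"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    is_control = (groups == "control").astype(float)
    cols = [is_control, 1.0 - is_control]
    names = ["control", "tbi"]
    for cov in covariates:
        v = cohort[cov].to_numpy(dtype=float)
        cols.append(v - v.mean())
        names.append(cov)
    return DesignMatrix(np.column_stack(cols), names)


def _check_design_rank(x: np.ndarray, columns) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns from the diagonal of R in a pivoted QR
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        tol = max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        collinear = [columns[i] for i in np.flatnonzero(diag <= tol)]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {collinear or columns}"
        )


def glm_contrast_ttest(y: np.ndarray, design: DesignMatrix, contrast) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS contrast t-test per feature.

    ``y`` is subjects x features; returns (t, two-sided parametric p, df)
    with t = c'beta / se(c'beta) and df the residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError("y rows must match design rows")
    n, k = x.shape
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than design columns ({k})")
    _check_design_rank(x, design.columns)
    c = np.asarray(contrast, dtype=float)
    if c.shape[0] == 2 and k > 2:
        c = design.full_contrast(c)
    if c.shape[0] != k:
        raise ValueError("contrast length must equal design column count")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    var_c = float(c @ xtx_inv @ c)
    est = c @ beta
    if var_c <= 0:
        t = np.zeros(y.shape[1])
        p = np.ones(y.shape[1])
    else:
        se = np.sqrt(var_c * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p, df


def permutation_pvalue(
    stat_fn,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Subject-label permutation p-value with the add-one estimator.

    ``stat_fn(labels)`` must return per-feature statistics; the p-value is
    p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm), which can never be zero.
    Deterministic given ``seed`` (or an explicit Generator).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    t_obs = np.atleast_1d(np.abs(np.asarray(stat_fn(labels), dtype=float)))
    count = np.zeros_like(t_obs)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        t_perm = np.atleast_1d(np.abs(np.asarray(stat_fn(perm), dtype=float)))
        count += t_perm >= t_obs
    return (1.0 + count) / (1.0 + n_perm)


def pooled_two_sample_t(m1, s1, n1, m2, s2, n2) -> float:
    """Pooled-variance Student t from group summaries (df = n1 + n2 - 2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        if m1 == m2:
            return 0.0
        raise ValueError("zero pooled variance with unequal means (infinite t)")
    return float((m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))


def hedges_g(t: float, n1: int, n2: int) -> tuple[float, tuple[float, float]]:
    """Hedges' g from a two-sample t statistic, with a 95% interval.

    g = J * t * sqrt(1/n1 + 1/n2), with the small-sample correction
    J = 1 - 3 / (4 (n1 + n2 - 2) - 1).  The interval is the normal
    approximation g +/- 1.96 * se(g), where
    se(g) = sqrt((n1 + n2) / (n1 n2) + g^2 / (2 (n1 + n2))).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    df = n1 + n2 - 2
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = float(j * t * np.sqrt(1.0 / n1 + 1.0 / n2))
    se = float(np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2))))
    return g, (g - 1.96 * se, g + 1.96 * se)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(z, v, rcond=None)
    return v - z @ beta


def adjusted_association(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    residualize: str = "both",
) -> dict:
    """Pearson and Spearman association after covariate removal.

    Both variables (default) or only ``x`` (``residualize='x_only'``) are
    residualized on [intercept, covariates] by least squares before the
    correlations are computed.  Returns a dict with r, s and their p-values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if residualize not in ("both", "x_only"):
        raise ValueError("residualize must be 'both' or 'x_only'")
    z = np.ones((x.size, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        z = np.column_stack([z, cov])
        if np.linalg.matrix_rank(z) < z.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
    rx = _residualize(x, z)
    ry = _residualize(y, z) if residualize == "both" else y - y.mean()
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero-variance residuals; association undefined")
    r, p_r = sps.pearsonr(rx, ry)
    s, p_s = sps.spearmanr(rx, ry)
    return {"r": float(r), "p_r": float(p_r), "s": float(s), "p_s": float(p_s)}


def group_comparison_table(
    values: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates=("age", "fd_mean"),
    contrast=CONTRAST_CONTROL_MINUS_TBI,
    n_perm: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted, permutation-corrected group comparison per feature.

    ``values`` is a subjects x features table aligned with ``cohort`` rows.
    The permutation statistic is the GLM contrast t itself, with covariates
    refit under every subject-label shuffle.  Features with permutation
    p >= alpha are flagged as not significant (the discard rule).
    """
    if list(values.index) != list(cohort.index):
        values = values.loc[cohort.index]
    design = design_from_cohort(cohort, covariates)
    y = values.to_numpy(dtype=float)
    t_obs, p_param, df = glm_contrast_ttest(y, design, contrast)

    is_control = (cohort["group"].to_numpy() == "control").astype(float)

    def stat(lbl):
        t, _, _ = glm_contrast_ttest(y, design.with_groups(lbl), contrast)
        return t

    p_perm = permutation_pvalue(stat, is_control, n_perm=n_perm, seed=seed)
    n1 = int(is_control.sum())
    n2 = int(len(is_control) - n1)
    rows = []
    for j, feat in enumerate(values.columns):
        g, (lo, hi) = hedges_g(float(t_obs[j]), n1, n2)
        rows.append(
            {
                "feature": feat,
                "t": float(t_obs[j]),
                "df": df,
                "p_param": float(p_param[j]),
                "p_perm": float(p_perm[j]),
                "g": g,
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(p_perm[j] < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
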