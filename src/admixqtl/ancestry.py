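"""Stepwise association of global and local ancestry with gene expression.

The procedure is a residual-on-residual cascade: inverse-normalized
expression is regressed on age, sex and asthma status (model 0); the
residuals are regressed on global ancestry theta (model 1); the model-1
residuals are regressed on the local ancestral allele count at the TSS
(model 2). Benjamini–Hochberg FDR is applied to the model-1 and model-2
p-values separately. A joint regression of the model-0 residuals on
global and local ancestry attributes variance via sequential sums of
squares, reported in both orders.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "inverse_normal_transform",
    "model0_residuals",
    "stepwise_ancestry_assoc",
    "joint_variance_explained",
]


def inverse_normal_transform(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Rank-based inverse normal transform (offset 0.5; ties get average ranks)."""
    x = np.asarray(x, dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, axis, x)
    n = x.shape[axis]
    return stats.norm.ppf((ranks - 0.5) / n)


def _design(covariates) -> np.ndarray:
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(C.shape[0]), C])


def _simple_regression(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Slope, two-sided p and R^2 of y ~ 1 + x; NaNs when x is constant."""
    n = y.size
    xc = x - x.mean()
    ssx = float(xc @ xc)
    if ssx <= 1e-12 * max(1.0, float(x @ x)):  # constant predictor up to rounding
        return np.nan, np.nan, np.nan
    yc = y - y.mean()
    ssy = float(yc @ yc)
    beta = float(xc @ yc) / ssx
    rss = ssy - beta**2 * ssx
    if ssy <= 0:
        return beta, np.nan, np.nan
    if rss <= 0:
        return beta, 0.0, 1.0
    se = np.sqrt(rss / (n - 2) / ssx)
    t = beta / se
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return beta, p, 1.0 - rss / ssy


def model0_residuals(expression: np.ndarray, covariates) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of inverse-normalized expression on the base covariates.

    Returns ``(residuals, constant_flags)``; a gene with constant
    expression yields all-zero residuals and is flagged instead of raised.
    """
    expr = np.atleast_2d(np.asarray(expression, dtype=float))
    X = _design(covariates)
    if np.any(~np.isfinite(X)):
        raise ValueError("covariates must be complete (no missing values)")
    H = X @ np.linalg.pinv(X)
    resid = np.empty_like(expr)
    flags = np.zeros(expr.shape[0], dtype=bool)
    for g in range(expr.shape[0]):
        if np.ptp(expr[g]) == 0:
            resid[g] = 0.0
            flags[g] = True
            continue
        y = inverse_normal_transform(expr[g])
        resid[g] = y - H @ y
    return resid, flags


def stepwise_ancestry_assoc(
    residuals: np.ndarray,
    theta: np.ndarray,
    local_anc: np.ndarray,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Sequential global-then-local ancestry regressions with per-step FDR.

    ``theta`` is the focal-ancestry global proportion (one value per
    sample); ``local_anc`` is the per-gene focal ancestral allele count at
    the TSS, shaped (n_genes, n_samples). Zero-variance predictors yield
    NA for that gene rather than an error.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    theta = np.asarray(theta, dtype=float)
    local_anc = np.atleast_2d(np.asarray(local_anc, dtype=float))
    G = residuals.shape[0]
    out = {k: np.full(G, np.nan) for k in ("beta_global", "p_global", "beta_local", "p_local")}
    for g in range(G):
        y = residuals[g]
        b1, p1, _ = _simple_regression(y, theta)
        out["beta_global"][g], out["p_global"][g] = b1, p1
        y1 = y - (b1 * (theta - theta.mean()) if np.isfinite(b1) else 0.0) - y.mean()
        b2, p2, _ = _simple_regression(y1, local_anc[g])
        out["beta_local"][g], out["p_local"][g] = b2, p2
    df = pd.DataFrame(out)
    for step in ("global", "local"):
        p = df[f"p_{step}"].to_numpy()
        q = np.full(G, np.nan)
        ok = np.isfinite(p)
        if ok.sum():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        df[f"q_{step}"] = q
        df[f"sig_{step}"] = q < fdr
    return df


def joint_variance_explained(
    residuals: np.ndarray,
    theta: np.ndarray,
    local_anc: np.ndarray,
    collinear_r2: float = 0.999,
) -> pd.DataFrame:
    """Joint-model R^2 attribution to global and local ancestry.

    Sequential sums of squares in both orders: ``r2_global`` and
    ``r2_local_incr`` take global first; ``r2_local`` and
    ``r2_global_incr`` take local first. When theta and the local count
    are (near-)collinear the incremental terms are reported with
    ``collinear=True``.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    theta = np.asarray(theta, dtype=float)
    local_anc = np.atleast_2d(np.asarray(local_anc, dtype=float))
    rows = []
    for g in range(residuals.shape[0]):
        y = residuals[g]
        l = local_anc[g]
        _, _, r2_g = _simple_regression(y, theta)
        _, _, r2_l = _simple_regression(y, l)
        X = np.column_stack([np.ones_like(theta), theta, l])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        fit = X @ beta
        ssy = float(((y - y.mean()) ** 2).sum())
        r2_joint = float(((fit - fit.mean()) ** 2).sum()) / ssy if ssy > 0 else np.nan
        with np.errstate(invalid="ignore"):
            r_tl = np.corrcoef(theta, l)[0, 1] if np.std(theta) > 0 and np.std(l) > 0 else np.nan
        collinear = (rank < 3) or (np.isfinite(r_tl) and r_tl**2 > collinear_r2)
        rows.append(
            {
                "r2_global": r2_g,
                "r2_local_incr": max(r2_joint - r2_g, 0.0) if np.isfinite(r2_joint) else np.nan,
                "r2_local": r2_l,
                "r2_global_incr": max(r2_joint - r2_l, 0.0) if np.isfinite(r2_joint) else np.nan,
                "r2_joint": r2_joint,
                "collinear": bool(collinear),
            }
        )
    return pd.DataFrame(rows)
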