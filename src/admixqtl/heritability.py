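"""Cis-heritability and genetic variance of expression via unconstrained REML.

A gene's cis genetic variance is modeled with one or more genetic
relationship matrices built from common variants in the window around the
TSS: ``y = X b + sum_k u_k + e`` with ``Var(y) = sum_k sigma2_k K_k +
sigma2_e I``. Estimation is restricted maximum likelihood with
average-information updates and an EM fallback, without a positivity
constraint on the genetic components (estimates may be negative, which
keeps group medians unbiased). The significance of the genetic component
is assessed with a likelihood-ratio test against the boundary null using
the 1/2 chi2_0 + 1/2 chi2_1 mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CisKinship",
    "RemlFit",
    "GroupComparison",
    "NoInformativeVariantsError",
    "build_kinship",
    "reml_fit",
    "compare_groups",
]


class NoInformativeVariantsError(ValueError):
    """No variants survive the MAF / pruning filters."""


@dataclass
class CisKinship:
    """Genetic relationship matrix for one gene's cis window."""

    matrix: np.ndarray
    n_variants: int
    method: str  # "standardized" | "ldak_thin"
    maf_min: float
    kept: np.ndarray  # indices (into the input dosage columns) of variants used


def _standardize(dosage: np.ndarray) -> np.ndarray:
    p = dosage.mean(axis=0) / 2.0
    return (dosage - 2 * p) / np.sqrt(2 * p * (1 - p))


def _ldak_thin(dosage: np.ndarray, positions: np.ndarray, r2_max: float = 0.98, window_bp: int = 100_000) -> np.ndarray:
    """Greedy duplicate-SNP pruning: drop one of each pair with r2 > r2_max
    within the window, keeping the earlier variant."""
    z = _standardize(dosage)
    n = z.shape[0]
    kept: list[int] = []
    for j in range(z.shape[1]):
        drop = False
        for i in reversed(kept):
            if positions[j] - positions[i] > window_bp:
                break
            r = float(z[:, i] @ z[:, j]) / n
            if r * r > r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
    return np.asarray(kept, dtype=int)


def build_kinship(
    dosage_cis: np.ndarray,
    maf_min: float = 0.01,
    method: str = "standardized",
    positions: np.ndarray | None = None,
) -> CisKinship:
    """Kinship ``K = Z Z' / m`` from allele-frequency-standardized dosages.

    Columns are standardized as ``(g - 2p) / sqrt(2 p (1 - p))``. Variants
    with MAF below ``maf_min`` (or monomorphic) are excluded first. With
    ``method="ldak_thin"`` near-duplicate variants (r2 > 0.98 within
    100 kb) are greedily removed before standardization, which requires
    ``positions``.
    """
    if method not in ("standardized", "ldak_thin"):
        raise ValueError(f"unknown kinship method {method!r}")
    dosage_cis = np.asarray(dosage_cis, dtype=float)
    p = dosage_cis.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = np.flatnonzero(maf >= maf_min)
    if keep.size == 0:
        raise NoInformativeVariantsError("no informative variants: all below MAF threshold or monomorphic")
    X = dosage_cis[:, keep]
    if method == "ldak_thin":
        if positions is None:
            raise ValueError("ldak_thin requires variant positions")
        sub = _ldak_thin(X, np.asarray(positions)[keep])
        keep = keep[sub]
        X = dosage_cis[:, keep]
    Z = _standardize(X)
    K = Z @ Z.T / Z.shape[1]
    return CisKinship(matrix=K, n_variants=int(keep.size), method=method, maf_min=maf_min, kept=keep)


@dataclass
class RemlFit:
    """Unconstrained REML variance components for one gene / group.

    ``sigma2_g`` is a scalar for a single kinship and an array for a
    multi-component (e.g. MAF-bin partitioned) fit; ``V_G`` is the total
    genetic variance and ``h2 = V_G / (V_G + sigma2_e)``.
    """

    sigma2_g: float | np.ndarray
    sigma2_e: float
    h2: float
    V_G: float
    logL: float
    logL0: float
    lrt: float
    lrt_p: float
    converged: bool
    n_iterations: int


def _reml_core(A_diags, y, X, max_iter, tol, constrain):
    """AI-REML over variance components with diagonal covariance building
    blocks (the single-kinship case is rotated into the kinship eigenbasis
    beforehand; the last component is the residual, with diagonal of ones)."""
    n, p = X.shape
    n_comp = len(A_diags)
    vary = float(np.var(y, ddof=1))
    sigma = np.full(n_comp, vary / n_comp)

    def loglik(sig):
        d = sum(s * a for s, a in zip(sig, A_diags))
        if np.min(d) <= 0:
            return None
        Vi = 1.0 / d
        XtViX = X.T @ (Vi[:, None] * X)
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        try:
            XtViX_inv = np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            return None
        Viy = Vi * y
        Py = Viy - Vi * (X @ (XtViX_inv @ (X.T @ Viy)))
        ll = -0.5 * (np.sum(np.log(d)) + logdet_x + float(y @ Py))
        return ll, d, Vi, XtViX_inv, Py

    state = loglik(sigma)
    if state is None:
        raise RuntimeError("invalid starting point for REML")
    ll = state[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, d, Vi, XtViX_inv, Py = state

        def P_apply(v):
            Viv = Vi * v
            return Viv - Vi * (X @ (XtViX_inv @ (X.T @ Viv)))

        grad = np.empty(n_comp)
        PAy = [a * Py for a in A_diags]
        # tr(P A) = tr(V^-1 A) - tr(XtViX^-1 X' V^-1 A V^-1 X)
        for k, a in enumerate(A_diags):
            tr_PA = float(np.sum(Vi * a)) - float(np.einsum("ij,ji->", XtViX_inv, X.T @ ((Vi**2 * a)[:, None] * X)))
            grad[k] = -0.5 * (tr_PA - float(Py @ (a * Py)))
        AI = np.empty((n_comp, n_comp))
        PPAy = [P_apply(v) for v in PAy]
        for k in range(n_comp):
            for l in range(k, n_comp):
                AI[k, l] = AI[l, k] = 0.5 * float(PAy[k] @ PPAy[l])

        try:
            delta = np.linalg.solve(AI, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(AI, grad, rcond=None)[0]
        if it == 1:
            # one damped first step stabilizes poor starting values
            delta = 0.5 * delta

        step = delta.copy()
        new_state, cand = None, sigma
        for _ in range(20):
            cand = sigma + step
            if constrain:
                cand = np.maximum(cand, 1e-8 * vary)
            new_state = loglik(cand)
            if new_state is not None and new_state[0] >= ll - 1e-10:
                break
            step *= 0.5
            new_state = None
        if new_state is None:
            # EM fallback: sigma_k' = sigma_k + sigma_k^2 (y'PA_kPy - tr(PA_k)) / n
            cand = sigma.copy()
            for k, a in enumerate(A_diags):
                tr_PA = float(np.sum(Vi * a)) - float(
                    np.einsum("ij,ji->", XtViX_inv, X.T @ ((Vi**2 * a)[:, None] * X))
                )
                cand[k] = sigma[k] + sigma[k] ** 2 * (float(Py @ (a * Py)) - tr_PA) / n
            if constrain:
                cand = np.maximum(cand, 1e-8 * vary)
            new_state = loglik(cand)
            if new_state is None:
                break
        new_ll = new_state[0]
        done = abs(new_ll - ll) < tol * max(1.0, abs(ll))
        sigma, state, ll = np.asarray(cand, dtype=float), new_state, new_ll
        if done:
            converged = True
            break
    return sigma, ll, converged, it


def _null_logL(y, X):
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("singular covariate design")
    resid = y - X @ beta
    rss = float(resid @ resid)
    sig = rss / (n - p)
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * np.log(sig) + logdet_xx + (n - p)), sig


def reml_fit(
    kinships: CisKinship | Sequence[CisKinship],
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    constrain: bool = False,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> RemlFit:
    """Fit variance components by unconstrained AI-REML with EM fallback.

    Multiple kinships give a joint multi-component fit (e.g. MAF-bin
    partitioning); ``V_G`` is then the sum of the per-component genetic
    variances. Convergence is declared when the relative restricted
    log-likelihood change drops below ``tol``; non-convergence is flagged
    on the returned fit rather than raised.
    """
    if isinstance(kinships, CisKinship):
        kinships = [kinships]
    Ks = [k.matrix for k in kinships]
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate design")

    if len(Ks) == 1:
        lam, U = np.linalg.eigh(Ks[0])
        ystar = U.T @ y
        Xstar = U.T @ X
        A_diags = [lam, np.ones(n)]
        sigma, ll, converged, it = _reml_core(A_diags, ystar, Xstar, max_iter, tol, constrain)
        logL0, _ = _null_logL(ystar, Xstar)
        sigma2_g: float | np.ndarray = float(sigma[0])
        vg_total = float(sigma[0])
    else:
        # joint diagonalization is not available for several kinships; work in
        # the eigenbasis of their sum only when they commute, else brute force
        # via a generalized decomposition is overkill at these sizes -- run the
        # same AI-REML on full matrices through repeated eigen-free algebra.
        sigma, ll, converged, it, logL0 = _reml_full(Ks, y, X, max_iter, tol, constrain)
        sigma2_g = sigma[:-1].copy()
        vg_total = float(sigma[:-1].sum())
    sigma2_e = float(sigma[-1])
    tot = vg_total + sigma2_e
    h2 = vg_total / tot if tot > 0 else np.nan
    lrt = 2.0 * (ll - logL0)
    lrt_p = 1.0 if lrt <= 1e-8 else 0.5 * float(stats.chi2.sf(lrt, 1))
    return RemlFit(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        h2=h2,
        V_G=vg_total,
        logL=float(ll),
        logL0=float(logL0),
        lrt=float(lrt),
        lrt_p=lrt_p,
        converged=bool(converged),
        n_iterations=it,
    )


def _reml_full(Ks, y, X, max_iter, tol, constrain):
    """AI-REML with dense covariance components (multi-kinship fits)."""
    n, p = X.shape
    As = [np.asarray(K, dtype=float) for K in Ks] + [np.eye(n)]
    n_comp = len(As)
    vary = float(np.var(y, ddof=1))
    sigma = np.full(n_comp, vary / n_comp)

    def loglik(sig):
        V = sum(s * A for s, A in zip(sig, As))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        XtViX_inv = np.linalg.inv(XtViX)
        P = Vi - Vi @ X @ XtViX_inv @ X.T @ Vi
        Py = P @ y
        ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
        return ll, P, Py

    state = loglik(sigma)
    if state is None:
        raise RuntimeError("invalid starting point for REML")
    ll = state[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, P, Py = state
        grad = np.empty(n_comp)
        PAy = [A @ Py for A in As]
        for k, A in enumerate(As):
            grad[k] = -0.5 * (float(np.einsum("ij,ji->", P, A)) - float(Py @ PAy[k]))
        AI = np.empty((n_comp, n_comp))
        PPAy = [P @ v for v in PAy]
        for k in range(n_comp):
            for l in range(k, n_comp):
                AI[k, l] = AI[l, k] = 0.5 * float(PAy[k] @ PPAy[l])
        try:
            delta = np.linalg.solve(AI, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(AI, grad, rcond=None)[0]
        if it == 1:
            delta = 0.5 * delta
        step = delta.copy()
        new_state, cand = None, sigma
        for _ in range(20):
            cand = sigma + step
            if constrain:
                cand = np.maximum(cand, 1e-8 * vary)
            new_state = loglik(cand)
            if new_state is not None and new_state[0] >= ll - 1e-10:
                break
            step *= 0.5
            new_state = None
        if new_state is None:
            cand = sigma.copy()
            for k, A in enumerate(As):
                tr_PA = float(np.einsum("ij,ji->", P, A))
                cand[k] = sigma[k] + sigma[k] ** 2 * (float(Py @ PAy[k]) - tr_PA) / n
            if constrain:
                cand = np.maximum(cand, 1e-8 * vary)
            new_state = loglik(cand)
            if new_state is None:
                break
        new_ll = new_state[0]
        done = abs(new_ll - ll) < tol * max(1.0, abs(ll))
        sigma, state, ll = np.asarray(cand, dtype=float), new_state, new_ll
        if done:
            converged = True
            break
    logL0, _ = _null_logL(y, X)
    return sigma, ll, converged, it, logL0


@dataclass
class GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two groups of estimates."""

    statistic: float  # rank sum of group A
    z: float
    p: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def compare_groups(estimates_a: Sequence[float], estimates_b: Sequence[float]) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test with normal approximation and tie
    correction; a fully tied comparison returns p = 1."""
    a = np.asarray(estimates_a, dtype=float)
    b = np.asarray(estimates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = stats.rankdata(np.concatenate([a, b]))
    W = float(ranks[:n_a].sum())
    mean_w = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        z, p = 0.0, 1.0
    else:
        z = (W - mean_w) / np.sqrt(var_w)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    return GroupComparison(
        statistic=W, z=float(z), p=min(p, 1.0),
        median_a=float(np.median(a)), median_b=float(np.median(b)), n_a=n_a, n_b=n_b,
    )
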