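"""Fine-mapping primitives for the ancestry-specific eQTL framework.

Three statistical tools feed the tier classifier:

* single-causal-variant posteriors from approximate Bayes factors
  (Wakefield form) and the 95% credible sets built from them,
* a simplified cross-population configuration posterior under one causal
  variant per ancestry group (is the signal specific to the high group,
  the low group, or shared?), and
* Cochran's Q test for effect-size heterogeneity between groups under a
  fixed-effect model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "CredibleSet",
    "ConfigPosterior",
    "HeterogeneityTest",
    "single_causal_posterior",
    "credible_set",
    "credible_sets_overlap",
    "config_posterior",
    "cochran_q",
    "DEFAULT_PRIOR_SD",
]

DEFAULT_PRIOR_SD = 0.15  # prior s.d. of the causal effect on the standardized scale


def _log_abf(z: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor per variant."""
    W = prior_sd**2
    se2 = se**2
    shrink = se2 / (se2 + W)
    return 0.5 * np.log(shrink) + 0.5 * z**2 * (W / (se2 + W))


def single_causal_posterior(
    z_scores: np.ndarray,
    sample_size: int | None = None,
    se: np.ndarray | None = None,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> np.ndarray:
    """Per-variant posterior probability under exactly one causal variant.

    Each variant's evidence is the Wakefield approximate Bayes factor
    ``sqrt(se^2/(se^2+W)) * exp(z^2 W / (2 (se^2+W)))`` with prior effect
    variance ``W = prior_sd^2``; under the single-causal assumption the
    posterior is the normalized Bayes factor vector. When standard errors
    are not supplied they default to ``1/sqrt(n)``, the marginal s.e. of a
    standardized effect.
    """
    z = np.asarray(z_scores, dtype=float)
    if se is None:
        if sample_size is None:
            raise ValueError("provide sample_size or per-variant se")
        se = np.full(z.shape, 1.0 / np.sqrt(sample_size))
    se = np.asarray(se, dtype=float)
    log_bf = _log_abf(z, se, prior_sd)
    ok = np.isfinite(log_bf)
    if not ok.any():
        raise ValueError("all Bayes factors are non-finite")
    log_bf = np.where(ok, log_bf, -np.inf)
    return np.exp(log_bf - logsumexp(log_bf))


@dataclass
class CredibleSet:
    """Minimal set of variants whose posteriors cumulate to the level."""

    members: np.ndarray  # variant indices, sorted by PP descending
    pp: np.ndarray  # posterior probability of each member
    level: float
    cumulative: float

    def __contains__(self, idx: int) -> bool:
        return idx in set(self.members.tolist())


def credible_set(
    pp_vector: np.ndarray,
    level: float = 0.95,
    positions: np.ndarray | None = None,
) -> CredibleSet:
    """Smallest prefix of the PP-sorted variants reaching the level.

    Ties in PP are broken by genomic position (lower first) when positions
    are given, otherwise by index, so the output is deterministic.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    pp = np.asarray(pp_vector, dtype=float)
    if abs(pp.sum() - 1.0) > 1e-6:
        raise ValueError("posterior probabilities must sum to 1")
    tiebreak = np.asarray(positions) if positions is not None else np.arange(pp.size)
    order = np.lexsort((tiebreak, -pp))
    csum = np.cumsum(pp[order])
    k = int(np.searchsorted(csum, level - 1e-12) + 1)
    k = min(k, pp.size)
    members = order[:k]
    return CredibleSet(members=members, pp=pp[members], level=level, cumulative=float(csum[k - 1]))


def credible_sets_overlap(cs_high: CredibleSet, cs_low: CredibleSet) -> bool:
    """True iff the two credible sets share at least one variant."""
    return bool(set(cs_high.members.tolist()) & set(cs_low.members.tolist()))


@dataclass
class ConfigPosterior:
    """Cross-population causal-configuration posterior per variant.

    For each variant: the probability the eQTL signal is specific to the
    high-ancestry group (``pp_high``), specific to the low group
    (``pp_low``), or shared (``pp_shared``). The three, together with the
    probability the variant is causal nowhere, sum to 1.
    """

    pp_high: np.ndarray
    pp_low: np.ndarray
    pp_shared: np.ndarray
    post_high: np.ndarray  # per-group posterior that each variant is the causal one
    post_low: np.ndarray
    null_high: float  # per-group posterior that no variant is causal
    null_low: float


def config_posterior(
    z_high: np.ndarray,
    z_low: np.ndarray,
    n_high: int | None = None,
    n_low: int | None = None,
    se_high: np.ndarray | None = None,
    se_low: np.ndarray | None = None,
    prior_sd: float = DEFAULT_PRIOR_SD,
    prior_null: float | None = None,
) -> ConfigPosterior:
    """Simplified two-population fine-mapping posterior.

    Each group carries at most one causal variant. Within a group the
    posterior over configurations (no causal variant, or causal at variant
    j) is proportional to the prior times the Wakefield Bayes factor; by
    default the prior is uniform over the M + 1 configurations. The two
    groups are independent given the configuration, so for variant j:
    ``pp_shared = P(causal in both at j)``, ``pp_high = P(causal at j in
    high, not causal at j in low)`` and symmetrically for ``pp_low``.
    """
    z_high = np.asarray(z_high, dtype=float)
    z_low = np.asarray(z_low, dtype=float)
    if z_high.shape != z_low.shape:
        raise ValueError("variant sets are misaligned between groups")
    m = z_high.size

    def group_post(z, n, se):
        if se is None:
            if n is None:
                raise ValueError("provide sample sizes or standard errors")
            se = np.full(m, 1.0 / np.sqrt(n))
        log_bf = _log_abf(z, np.asarray(se, dtype=float), prior_sd)
        pn = 1.0 / (m + 1) if prior_null is None else prior_null
        pc = (1.0 - pn) / m  # per-variant causal prior
        logw = np.concatenate([[np.log(pn)], np.log(pc) + log_bf])
        logw -= logsumexp(logw)
        w = np.exp(logw)
        return w[0], w[1:]

    null_h, post_h = group_post(z_high, n_high, se_high)
    null_l, post_l = group_post(z_low, n_low, se_low)
    pp_shared = post_h * post_l
    pp_high = post_h * (1.0 - post_l)
    pp_low = (1.0 - post_h) * post_l
    return ConfigPosterior(
        pp_high=pp_high,
        pp_low=pp_low,
        pp_shared=pp_shared,
        post_high=post_h,
        post_low=post_l,
        null_high=float(null_h),
        null_low=float(null_l),
    )


@dataclass
class HeterogeneityTest:
    """Cochran's Q heterogeneity test between group effect estimates."""

    Q: float
    df: int
    p: float


def cochran_q(
    beta_high: float | Sequence[float],
    se_high: float | Sequence[float],
    beta_low: float | Sequence[float],
    se_low: float | Sequence[float],
) -> HeterogeneityTest | list[HeterogeneityTest]:
    """Two-group Cochran's Q: ``(b_h - b_l)^2 / (se_h^2 + se_l^2)``, chi2(1).

    The statistic is the fixed-effect heterogeneity sum
    ``sum_i w_i (b_i - b_FE)^2`` with inverse-variance weights, which for
    two groups reduces to the closed form above. Vector inputs give a list
    of tests.
    """
    bh = np.atleast_1d(np.asarray(beta_high, dtype=float))
    sh = np.atleast_1d(np.asarray(se_high, dtype=float))
    bl = np.atleast_1d(np.asarray(beta_low, dtype=float))
    sl = np.atleast_1d(np.asarray(se_low, dtype=float))
    if np.any(sh <= 0) or np.any(sl <= 0):
        raise ValueError("standard errors must be positive")
    Q = (bh - bl) ** 2 / (sh**2 + sl**2)
    p = stats.chi2.sf(Q, 1)
    tests = [HeterogeneityTest(Q=float(q), df=1, p=float(pv)) for q, pv in zip(Q, p)]
    return tests[0] if np.isscalar(beta_high) or np.asarray(beta_high).ndim == 0 else tests
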