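"""End-to-end ancestry-contrast eQTL mapping and anc-eQTL classification.

``run_contrast`` reproduces the full per-contrast protocol on a simulated
(or user-supplied) cohort: split samples into high (> 50%) and low
(< 10%) global-ancestry groups for the focal population, run the
covariate-corrected cis scan and adaptive permutation calibration in each
group, call eGenes at the study FDR, fine-map each eligible gene with
single-causal posteriors and 95% credible sets, compute cross-population
configuration posteriors (after pruning variant pairs with r2 > 0.95 in
both groups) and per-variant Cochran's Q tests, and classify each gene
with the tier decision tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import eqtl, finemap
from .classify import AncEqtlCall, classify_gene
from .simulate import AdmixedCohort, ExpressionDataset

__all__ = ["ContrastResult", "run_contrast"]


@dataclass
class ContrastResult:
    """Classification calls plus the per-group mapping intermediates."""

    calls: list[AncEqtlCall]
    calls_df: pd.DataFrame
    egenes_high: pd.DataFrame
    egenes_low: pd.DataFrame
    n_gene_tier3: int
    idx_high: np.ndarray
    idx_low: np.ndarray


def _prune_both_groups(Xh: np.ndarray, Xl: np.ndarray, p_high: np.ndarray, r2_cut: float = 0.95):
    """Remove one of each variant pair with r2 > r2_cut in BOTH groups.

    Variants are visited in order of the high-group nominal p-value; a
    variant is dropped when it is near-duplicate (in both groups) of an
    already-kept variant, which then becomes its representative.
    """

    def corr2(X):
        xc = X - X.mean(axis=0)
        norm = np.sqrt((xc**2).sum(axis=0))
        norm[norm == 0] = np.inf
        r = (xc / norm).T @ (xc / norm)
        return r**2

    r2h = corr2(Xh)
    r2l = corr2(Xl)
    order = np.argsort(p_high, kind="stable")
    kept: list[int] = []
    rep = np.full(p_high.size, -1, dtype=int)
    for j in order:
        dup = None
        for i in kept:
            if r2h[i, j] > r2_cut and r2l[i, j] > r2_cut:
                dup = i
                break
        if dup is None:
            kept.append(j)
            rep[j] = j
        else:
            rep[j] = dup
    return np.asarray(kept, dtype=int), rep


def run_contrast(
    cohort: AdmixedCohort,
    expression: ExpressionDataset,
    focal_pop: int = 0,
    high_cut: float = 0.5,
    low_cut: float = 0.1,
    fdr: float = 0.05,
    n_hidden_factors: int = 5,
    max_permutations: int = 1000,
    maf_min: float = 0.01,
    level: float = 0.95,
    prior_sd: float = finemap.DEFAULT_PRIOR_SD,
    strict_tier1: bool = False,
    eligible: np.ndarray | None = None,
    seed: int = 0,
) -> ContrastResult:
    """Run the complete anc-eQTL contrast for one focal ancestry.

    ``eligible`` marks genes entering classification (e.g. heritable
    protein-coding eGenes); by default every high-group eGene is eligible.
    ``n_gene`` for the tier-3 Bonferroni divisor is the number of genes
    reaching the overlapping-credible-sets step.
    """
    panel = cohort.panel
    theta = cohort.theta[:, focal_pop]
    idx_high = np.flatnonzero(theta > high_cut)
    idx_low = np.flatnonzero(theta < low_cut)
    if idx_high.size < 10 or idx_low.size < 10:
        raise ValueError("high/low ancestry groups are too small for a contrast")
    cov = cohort.covariates[["age", "sex", "asthma"]].to_numpy(dtype=float)

    corr = {}
    for tag, idx in (("high", idx_high), ("low", idx_low)):
        corr[tag] = eqtl.prepare_expression(expression.expr[:, idx], cov[idx], n_hidden_factors)

    G = panel.n_genes
    scans: dict[str, list] = {"high": [], "low": []}
    cals: dict[str, list] = {"high": [], "low": []}
    for g in range(G):
        win = panel.gene_variants(g)
        for tag, idx in (("high", idx_high), ("low", idx_low)):
            D = cohort.dosage[np.ix_(idx, win)]
            y = corr[tag][g]
            scan = eqtl.cis_scan(panel.gene_ids[g], D, y, maf_min=maf_min)
            scan.variant_idx = win[scan.variant_idx]  # lift to panel indexing
            scans[tag].append(scan)
            cals[tag].append(
                eqtl.permute_calibrate(
                    panel.gene_ids[g], y, D,
                    max_permutations=max_permutations,
                    seed=(int(seed) * 1000003 + g * 2 + (tag == "low")) % (2**31),
                    maf_min=maf_min,
                )
            )
    egenes_high = eqtl.egene_fdr(cals["high"], fdr=fdr)
    egenes_low = eqtl.egene_fdr(cals["low"], fdr=fdr)
    is_egene_high = egenes_high.set_index("gene_id")["is_egene"]
    is_egene_low = egenes_low.set_index("gene_id")["is_egene"]

    if eligible is None:
        eligible = np.ones(G, dtype=bool)

    # fine-map every eligible high-group eGene in both groups
    gene_state = []
    for g in range(G):
        gid = panel.gene_ids[g]
        if not (eligible[g] and bool(is_egene_high.get(gid, False))):
            gene_state.append(None)
            continue
        sh = scans["high"][g]
        pp_h = finemap.single_causal_posterior(sh.t, sample_size=sh.n, prior_sd=prior_sd)
        cs_h = finemap.credible_set(pp_h, level=level, positions=panel.positions[sh.variant_idx])
        cs_h_global = finemap.CredibleSet(
            members=sh.variant_idx[cs_h.members], pp=cs_h.pp, level=level, cumulative=cs_h.cumulative
        )
        cs_l_global = None
        if bool(is_egene_low.get(gid, False)):
            sl = scans["low"][g]
            pp_l = finemap.single_causal_posterior(sl.t, sample_size=sl.n, prior_sd=prior_sd)
            cs_l = finemap.credible_set(pp_l, level=level, positions=panel.positions[sl.variant_idx])
            cs_l_global = finemap.CredibleSet(
                members=sl.variant_idx[cs_l.members], pp=cs_l.pp, level=level, cumulative=cs_l.cumulative
            )
        gene_state.append((cs_h_global, cs_l_global))

    # Bonferroni divisor: genes reaching the overlapping-sets (tier 3) step
    n_gene_tier3 = sum(
        1
        for st in gene_state
        if st is not None and st[1] is not None and finemap.credible_sets_overlap(st[0], st[1])
    )

    calls: list[AncEqtlCall] = []
    contrast = f"{panel.pop_labels[focal_pop]}_high_vs_low"
    for g in range(G):
        st = gene_state[g]
        if st is None:
            continue
        cs_h, cs_l = st
        sh, sl = scans["high"][g], scans["low"][g]
        win = panel.gene_variants(g)
        maf_high = np.full(panel.n_variants, np.nan)
        maf_low = np.full(panel.n_variants, np.nan)
        maf_high[win] = cohort.maf(win, rows=idx_high)
        maf_low[win] = cohort.maf(win, rows=idx_low)

        # cross-population posterior on variants tested in both groups,
        # after pruning pairs near-duplicate (r2 > 0.95) in BOTH groups
        common, hpos, lpos = np.intersect1d(sh.variant_idx, sl.variant_idx, return_indices=True)
        config = None
        pp_index = None
        if common.size:
            Xh = cohort.dosage[np.ix_(idx_high, common)]
            Xl = cohort.dosage[np.ix_(idx_low, common)]
            kept, rep = _prune_both_groups(Xh, Xl, sh.p[hpos])
            cp = finemap.config_posterior(
                sh.t[hpos][kept], sl.t[lpos][kept], n_high=sh.n, n_low=sl.n, prior_sd=prior_sd
            )
            # scatter back: a pruned-away variant inherits its representative
            pos_of = {int(k): i for i, k in enumerate(kept)}
            back = np.array([pos_of[int(r)] for r in rep])
            config = finemap.ConfigPosterior(
                pp_high=cp.pp_high[back],
                pp_low=cp.pp_low[back],
                pp_shared=cp.pp_shared[back],
                post_high=cp.post_high[back],
                post_low=cp.post_low[back],
                null_high=cp.null_high,
                null_low=cp.null_low,
            )
            pp_index = common

        het: dict[int, finemap.HeterogeneityTest] = {}
        if common.size:
            tests = finemap.cochran_q(sh.beta[hpos], sh.se[hpos], sl.beta[lpos], sl.se[lpos])
            het = {int(v): t for v, t in zip(common, tests)}

        calls.append(
            classify_gene(
                cs_h,
                cs_l,
                maf_high,
                maf_low,
                config,
                het,
                n_gene=n_gene_tier3,
                gene_id=panel.gene_ids[g],
                contrast=contrast,
                strict_tier1=strict_tier1,
                pp_index=pp_index,
            )
        )

    calls_df = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "contrast": c.contrast,
                "call": c.call,
                "lead_variant": c.lead_variant,
                "maf_high": c.maf_high,
                "maf_low": c.maf_low,
                "overlap": c.overlap,
                "max_pp_high": c.max_pp_high,
                "max_q_p": c.max_q_p,
                "flags": ";".join(c.flags),
            }
            for c in calls
        ]
    )
    return ContrastResult(
        calls=calls,
        calls_df=calls_df,
        egenes_high=egenes_high,
        egenes_low=egenes_low,
        n_gene_tier3=n_gene_tier3,
        idx_high=idx_high,
        idx_low=idx_low,
    )
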