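"""Tiered classification of ancestry-specific eQTLs.

For a heritable protein-coding eGene in the high-ancestry group, the
decision tree compares the 95% credible sets fine-mapped in the high and
low global-ancestry groups:

* nonoverlapping sets, lead variant common (MAF >= 0.01) in the high
  group but rare (< 0.01) or monomorphic in the low group -> **tier 1**
  (allele-frequency-driven, the most ancestry-specific class);
* nonoverlapping sets, variant common in both groups, cross-population
  configuration posterior concentrated on the high group (every
  credible-set member has PP_high > PP_low and PP_high > PP_shared, and
  the best member exceeds PP_high > 0.8) -> **tier 2** (LD-driven);
* overlapping sets with every credible-set member showing significant
  effect-size heterogeneity (Cochran's Q p < 0.05 / n_gene) -> **tier 3**;
* overlapping sets without heterogeneity -> **shared**; anything else ->
  **none**.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .finemap import ConfigPosterior, CredibleSet, HeterogeneityTest, credible_sets_overlap

__all__ = ["AncEqtlCall", "classify_gene", "prevalence", "TIERS"]

TIERS = ("tier1", "tier2", "tier3")
CALLS = TIERS + ("shared", "none")


@dataclass
class AncEqtlCall:
    """One gene's ancestry-specific eQTL call with its supporting evidence."""

    gene_id: str
    contrast: str
    call: str
    lead_variant: int
    maf_high: float
    maf_low: float
    overlap: bool
    max_pp_high: float
    max_q_p: float  # largest Q p among credible-set members (tier-3 evidence)
    n_gene: int
    flags: list[str] = field(default_factory=list)


def _maf_lookup(maf, idx: int) -> float:
    v = float(np.asarray(maf)[idx]) if not np.isscalar(maf) else float(maf)
    return v


def classify_gene(
    cs_high: CredibleSet,
    cs_low: CredibleSet | None,
    maf_high: np.ndarray,
    maf_low: np.ndarray,
    config_post: ConfigPosterior | None,
    het_tests: dict[int, HeterogeneityTest] | None,
    n_gene: int,
    gene_id: str = "",
    contrast: str = "",
    maf_common: float = 0.01,
    pp_threshold: float = 0.8,
    strict_tier1: bool = False,
    pp_index: np.ndarray | None = None,
) -> AncEqtlCall:
    """Apply the anc-eQTL decision tree to one gene.

    ``maf_high`` / ``maf_low`` are per-variant MAFs indexed like the
    credible-set members. ``config_post`` arrays are aligned to
    ``pp_index`` (defaults to direct indexing by member id).
    ``cs_low=None`` marks a gene with no detectable eQTL signal in the low
    group; such genes are classified through the high-group credible set
    alone and flagged ``low_group_silent``.
    """
    if cs_high is None:
        raise ValueError("missing fine-mapping input: high-group credible set")
    flags: list[str] = []
    lead = int(cs_high.members[0])
    maf_h_lead = _maf_lookup(maf_high, lead)
    maf_l_lead = _maf_lookup(maf_low, lead)

    def pp_of(member: int, arr: np.ndarray) -> float:
        if pp_index is not None:
            where = np.flatnonzero(np.asarray(pp_index) == member)
            return float(arr[where[0]]) if where.size else np.nan
        return float(arr[member])

    def tier1_ok() -> bool:
        check = cs_high.members if strict_tier1 else [lead]
        return all(
            _maf_lookup(maf_high, int(m)) >= maf_common and _maf_lookup(maf_low, int(m)) < maf_common
            for m in check
        )

    def tier2_eval() -> tuple[bool, float]:
        if config_post is None:
            raise ValueError("missing fine-mapping input: cross-population configuration posterior")
        pps = []
        dominant = True
        for m in cs_high.members:
            ph = pp_of(int(m), config_post.pp_high)
            pl = pp_of(int(m), config_post.pp_low)
            ps = pp_of(int(m), config_post.pp_shared)
            if not np.isfinite(ph):
                dominant = False
                continue
            pps.append(ph)
            if not (ph > pl and ph > ps):
                dominant = False
        best = float(np.nanmax(pps)) if pps else np.nan
        return dominant and np.isfinite(best) and best > pp_threshold, best

    max_pp_high = np.nan
    max_q_p = np.nan
    if cs_low is None:
        flags.append("low_group_silent")
        overlap = False
        if tier1_ok():
            call = "tier1"
        else:
            is_t2, max_pp_high = tier2_eval()
            call = "tier2" if is_t2 else "none"
    else:
        overlap = credible_sets_overlap(cs_high, cs_low)
        if not overlap:
            if tier1_ok():
                call = "tier1"
            else:
                is_t2, max_pp_high = tier2_eval()
                call = "tier2" if is_t2 else "none"
        else:
            if het_tests is None:
                raise ValueError("missing fine-mapping input: heterogeneity tests")
            alpha = 0.05 / max(n_gene, 1)
            qps = [het_tests[int(m)].p if int(m) in het_tests else np.nan for m in cs_high.members]
            max_q_p = float(np.nanmax(qps)) if np.any(np.isfinite(qps)) else np.nan
            all_het = all(np.isfinite(q) and q < alpha for q in qps)
            call = "tier3" if all_het else "shared"
    return AncEqtlCall(
        gene_id=gene_id,
        contrast=contrast,
        call=call,
        lead_variant=lead,
        maf_high=maf_h_lead,
        maf_low=maf_l_lead,
        overlap=overlap,
        max_pp_high=max_pp_high,
        max_q_p=max_q_p,
        n_gene=n_gene,
        flags=flags,
    )


def prevalence(
    calls: list[AncEqtlCall] | pd.DataFrame,
    gene_universe: list[str],
    denominator: str = "universe",
) -> pd.DataFrame:
    """Per-contrast prevalence of each tier and of any anc-eQTL.

    ``gene_universe`` defines the denominator (e.g. heritable
    protein-coding eGenes, or all protein-coding genes for the unfiltered
    secondary denominator). Genes in the universe without a call count as
    ``none``.
    """
    if len(gene_universe) == 0:
        raise ValueError("empty gene universe")
    if isinstance(calls, list):
        df = pd.DataFrame([{"gene_id": c.gene_id, "contrast": c.contrast, "call": c.call} for c in calls])
    else:
        df = calls[["gene_id", "contrast", "call"]].copy()
    df = df[df["gene_id"].isin(set(gene_universe))]
    n_total = len(gene_universe)
    rows = []
    for contrast, grp in df.groupby("contrast", dropna=False):
        counts = grp["call"].value_counts()
        any_tier = int(sum(counts.get(t, 0) for t in TIERS))
        row = {"contrast": contrast, "n_genes": n_total, "denominator": denominator}
        for t in TIERS:
            row[f"n_{t}"] = int(counts.get(t, 0))
            row[f"frac_{t}"] = counts.get(t, 0) / n_total
        row["n_any_tier"] = any_tier
        row["frac_any_tier"] = any_tier / n_total
        row["n_shared"] = int(counts.get("shared", 0))
        rows.append(row)
    return pd.DataFrame(rows)
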