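"""Synthetic admixed genotype–expression–trait cohorts with labeled truth.

The generator emulates the features of an admixed human cohort that matter
for ancestry-aware eQTL analysis:

* ancestral populations with divergent allele frequencies (Balding–Nichols
  drift model, per-population differentiation ``F``) including
  population-private common variants,
* per-individual global ancestry proportions (theta) and per-gene local
  ancestry allele counts at the TSS,
* block-wise LD induced by a Gaussian copula on haplotypes, with a
  per-ancestry within-block latent correlation so LD can differ between
  ancestral backgrounds,
* cis-eQTL architectures under labeled scenarios (``shared``, ``tier1``,
  ``tier2``, ``tier3``, ``null``) mirroring the ancestry-specific eQTL
  classes, and
* a downstream quantitative trait mediated by gene expression, summarized
  as GWAS summary statistics for TWAS testing.

All randomness flows from a single integer seed through named streams so
that each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "AncestralPanel",
    "AdmixedCohort",
    "ExpressionDataset",
    "SCENARIOS",
    "simulate_ancestral_panel",
    "simulate_admixed_genotypes",
    "simulate_expression",
    "simulate_gwas_sumstats",
    "two_group_theta",
]

SCENARIOS = ("null", "shared", "tier1", "tier2", "tier3")

# named RNG streams: every stage derives its generator from (seed, stream id)
_STREAMS = {
    "panel": 11,
    "genotypes": 23,
    "expression": 37,
    "gwas": 53,
    "theta": 71,
}

_BASES = np.array(list("ACGT"))


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream], int(extra)])


@dataclass
class AncestralPanel:
    """Ancestral allele frequencies, LD-block structure and gene anchors.

    Variants live on a single chromosome, partitioned into disjoint per-gene
    cis-regions; each region is subdivided into LD blocks. ``rho[b, k]`` is
    the latent within-block haplotype correlation for block ``b`` on an
    ancestry-``k`` background.
    """

    pop_labels: list[str]
    freq: np.ndarray  # (n_variants, n_pops)
    chrom: str
    positions: np.ndarray  # (n_variants,) 1-based, strictly increasing
    ref: np.ndarray  # (n_variants,) reference allele
    alt: np.ndarray  # (n_variants,) alternate (frequency-tracked) allele
    blocks: np.ndarray  # (n_blocks, 2) half-open variant-index ranges
    rho: np.ndarray  # (n_blocks, n_pops)
    gene_ids: list[str]
    tss: np.ndarray  # (n_genes,)
    gene_regions: np.ndarray  # (n_genes, 2) half-open variant-index ranges
    F: np.ndarray  # (n_pops,) Balding–Nichols differentiation
    private_pop: np.ndarray  # (n_variants,) host population of a private variant, -1 otherwise
    variant_ids: list[str] = field(default_factory=list)

    @property
    def n_pops(self) -> int:
        return len(self.pop_labels)

    @property
    def n_variants(self) -> int:
        return self.freq.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_variants(self, g: int) -> np.ndarray:
        lo, hi = self.gene_regions[g]
        return np.arange(lo, hi)

    def gene_blocks(self, g: int) -> np.ndarray:
        lo, hi = self.gene_regions[g]
        return np.flatnonzero((self.blocks[:, 0] >= lo) & (self.blocks[:, 1] <= hi))

    def validate(self) -> None:
        if not np.all(np.isfinite(self.freq)) or self.freq.min() < 0 or self.freq.max() > 1:
            raise ValueError("allele frequencies must be finite and in [0, 1]")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing within the chromosome")
        covered = np.zeros(self.n_variants, dtype=int)
        for lo, hi in self.blocks:
            covered[lo:hi] += 1
        if not np.all(covered == 1):
            raise ValueError("every variant must belong to exactly one LD block")


def simulate_ancestral_panel(
    n_pops: int = 3,
    n_variants: int = 2000,
    n_genes: int = 10,
    block_size: int = 20,
    rho_per_pop: Sequence[float] | float = 0.6,
    F: Sequence[float] | float = 0.15,
    seed: int = 0,
    private_fraction: float = 0.05,
    pop_labels: Sequence[str] | None = None,
    rho_override: Mapping[int, Sequence[float]] | None = None,
    window_bp: int = 500_000,
) -> AncestralPanel:
    """Draw an ancestral reference panel under the Balding–Nichols model.

    Per-variant frequencies start from a shared base frequency
    ``p ~ U(0.05, 0.95)`` and drift independently in each population as
    ``Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k)``; larger ``F_k`` models a
    stronger bottleneck (expected heterozygosity scales with ``1 - F_k``).
    A fraction of variants is forced population-private: common in one
    ancestry and at frequency < 0.01 in the others.

    Parameters
    ----------
    rho_per_pop
        Latent within-block correlation per population (scalar broadcasts).
    F
        Differentiation parameter per population in (0, 1); a scalar
        applies to all populations.
    rho_override
        Optional per-gene override ``{gene_index: rho_per_pop}`` applied to
        all blocks of that gene (used to plant ancestry-asymmetric LD).
    """
    if n_pops < 2:
        raise ValueError("n_pops must be >= 2")
    F = np.broadcast_to(np.asarray(F, dtype=float), (n_pops,)).copy()
    if np.any(F <= 0) or np.any(F >= 1):
        raise ValueError("F must lie in (0, 1)")
    rho = np.broadcast_to(np.asarray(rho_per_pop, dtype=float), (n_pops,)).copy()
    if np.any(rho < 0) or np.any(rho >= 1):
        raise ValueError("rho_per_pop must lie in [0, 1)")
    if pop_labels is None:
        pop_labels = [f"POP{k}" for k in range(n_pops)]
    pop_labels = list(pop_labels)

    rng = _rng(seed, "panel")

    # disjoint per-gene cis regions spaced 2 Mb apart on one chromosome
    counts = np.full(n_genes, n_variants // n_genes, dtype=int)
    counts[: n_variants % n_genes] += 1
    gene_regions = np.zeros((n_genes, 2), dtype=int)
    tss = np.zeros(n_genes, dtype=np.int64)
    positions = np.empty(n_variants, dtype=np.int64)
    start = 0
    for g in range(n_genes):
        center = 1_000_000 + 2_000_000 * g
        tss[g] = center
        m = counts[g]
        pos = np.sort(rng.choice(np.arange(center - window_bp, center + window_bp), size=m, replace=False))
        positions[start : start + m] = pos
        gene_regions[g] = (start, start + m)
        start += m

    base = rng.uniform(0.05, 0.95, size=n_variants)
    freq = np.empty((n_variants, n_pops))
    for k in range(n_pops):
        a = base * (1 - F[k]) / F[k]
        b = (1 - base) * (1 - F[k]) / F[k]
        freq[:, k] = rng.beta(a, b)

    private_pop = np.full(n_variants, -1, dtype=int)
    n_private = int(round(private_fraction * n_variants))
    if n_private > 0:
        idx = rng.choice(n_variants, size=n_private, replace=False)
        hosts = rng.integers(0, n_pops, size=n_private)
        private_pop[idx] = hosts
        freq[idx] = rng.uniform(0.0002, 0.002, size=(n_private, n_pops))
        # host frequency capped at 0.2 so that admixture leakage into a
        # low-ancestry group (< 10% global) keeps the variant rare there
        freq[idx, hosts] = rng.uniform(0.05, 0.2, size=n_private)

    # LD blocks nested within gene regions
    blocks = []
    block_rho = []
    for g in range(n_genes):
        lo, hi = gene_regions[g]
        rho_g = rho
        if rho_override is not None and g in rho_override:
            rho_g = np.broadcast_to(np.asarray(rho_override[g], dtype=float), (n_pops,))
            if np.any(rho_g < 0) or np.any(rho_g >= 1):
                raise ValueError("rho_override values must lie in [0, 1)")
        for b in range(lo, hi, block_size):
            blocks.append((b, min(b + block_size, hi)))
            block_rho.append(np.array(rho_g, dtype=float))
    blocks = np.array(blocks, dtype=int)
    block_rho = np.array(block_rho)

    ref_idx = rng.integers(0, 4, size=n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_variants)) % 4
    variant_ids = [f"var{j}_{positions[j]}" for j in range(n_variants)]

    panel = AncestralPanel(
        pop_labels=pop_labels,
        freq=freq,
        chrom="1",
        positions=positions,
        ref=_BASES[ref_idx],
        alt=_BASES[alt_idx],
        blocks=blocks,
        rho=block_rho,
        gene_ids=[f"GENE{g}" for g in range(n_genes)],
        tss=tss,
        gene_regions=gene_regions,
        F=F,
        private_pop=private_pop,
        variant_ids=variant_ids,
    )
    panel.validate()
    return panel


@dataclass
class AdmixedCohort:
    """Genotypes, ancestry and covariates for ``n`` admixed individuals.

    Haplotypes are retained (``haplotypes[i, h, j]`` is the allele carried
    by haplotype ``h`` of individual ``i`` at variant ``j``) together with
    the ancestral origin of each haplotype at each gene, so that
    local-ancestry-dependent effect sizes can be simulated exactly.
    """

    panel: AncestralPanel
    haplotypes: np.ndarray  # (n, 2, n_variants) uint8
    hap_ancestry: np.ndarray  # (n_genes, n, 2) int8
    theta: np.ndarray  # (n, n_pops)
    covariates: pd.DataFrame  # age, sex, asthma
    seed: int

    _dosage: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def dosage(self) -> np.ndarray:
        """n_individuals x n_variants alternate-allele dosage in [0, 2]."""
        if self._dosage is None:
            self._dosage = self.haplotypes.sum(axis=1).astype(float)
        return self._dosage

    @property
    def local_anc(self) -> np.ndarray:
        """(n_genes, n, n_pops) count of ancestral alleles at each gene's TSS."""
        n_pops = self.panel.n_pops
        counts = np.zeros((self.panel.n_genes, self.n_individuals, n_pops), dtype=np.int8)
        for k in range(n_pops):
            counts[:, :, k] = (self.hap_ancestry == k).sum(axis=2)
        return counts

    def sample_freq(self, idx: np.ndarray | slice = slice(None)) -> np.ndarray:
        return self.dosage[:, idx].mean(axis=0) / 2.0

    def maf(self, idx: np.ndarray | slice = slice(None), rows: np.ndarray | slice = slice(None)) -> np.ndarray:
        p = self.dosage[rows][:, idx].mean(axis=0) / 2.0
        return np.minimum(p, 1 - p)

    def validate(self) -> None:
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("global ancestry rows must sum to 1")
        la = self.local_anc
        if not np.all(la.sum(axis=2) == 2):
            raise ValueError("local ancestry rows must sum to 2")
        d = self.dosage
        if d.min() < 0 or d.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")


def two_group_theta(
    n: int,
    n_pops: int = 3,
    focal_pop: int = 0,
    high_frac: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Global-ancestry proportions with distinct high/low focal-ancestry strata.

    Roughly ``high_frac`` of individuals receive > 50% focal ancestry
    (drawn U(0.6, 0.95)) and the rest < 10% (U(0, 0.06), i.e. a
    low-ancestry stratum averaging ~3% focal ancestry, as typical for
    individuals below a 10% global-ancestry cut-off); the remaining
    ancestry mass is split uniformly among the other populations.
    """
    rng = _rng(seed, "theta")
    hi = rng.random(n) < high_frac
    focal = np.where(hi, rng.uniform(0.6, 0.95, n), rng.uniform(0.0, 0.06, n))
    rest = rng.dirichlet(np.ones(n_pops - 1), size=n) * (1 - focal)[:, None]
    theta = np.empty((n, n_pops))
    theta[:, focal_pop] = focal
    others = [k for k in range(n_pops) if k != focal_pop]
    theta[:, others] = rest
    return theta


def _resolve_theta(theta, n: int, n_pops: int, seed: int) -> np.ndarray:
    if callable(theta):
        out = np.asarray(theta(_rng(seed, "theta"), n), dtype=float)
    else:
        arr = np.asarray(theta, dtype=float)
        if arr.ndim == 2:
            out = arr
        elif arr.ndim == 1 and arr.size == n_pops:
            if abs(arr.sum() - 1.0) < 1e-9:
                out = np.tile(arr, (n, 1))  # fixed proportions for everyone
            else:
                out = _rng(seed, "theta").dirichlet(arr, size=n)
        else:
            raise ValueError("theta must be (n, n_pops), a length-n_pops vector, or a callable")
    if out.shape != (n, n_pops):
        raise ValueError(f"theta has shape {out.shape}, expected {(n, n_pops)}")
    if np.any(out < 0) or not np.allclose(out.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("theta rows must be probability vectors")
    return out / out.sum(axis=1, keepdims=True)


def simulate_admixed_genotypes(
    panel: AncestralPanel,
    n_individuals: int,
    theta: Sequence[float] | np.ndarray | Callable = (1.0, 1.0, 1.0),
    seed: int = 0,
) -> AdmixedCohort:
    """Draw haplotypes for an admixed cohort from the ancestral panel.

    For each gene and haplotype, a local ancestry is drawn from the
    individual's global proportions theta; alleles across the gene's cis
    region are then drawn from that ancestry's frequencies with block LD
    induced by an equicorrelated Gaussian copula at that ancestry's rho.
    The Gaussian copula preserves the marginal allele frequency exactly
    while giving within-block correlation that increases with rho.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    n = n_individuals
    n_pops = panel.n_pops
    G = panel.n_genes
    theta = _resolve_theta(theta, n, n_pops, seed)
    rng = _rng(seed, "genotypes")

    # local ancestry of each haplotype at each gene
    u = rng.random((G, n, 2))
    cum = np.cumsum(theta, axis=1)  # (n, n_pops)
    hap_anc = (u[..., None] >= cum[None, :, None, :]).sum(axis=3).astype(np.int8)

    haplotypes = np.zeros((n, 2, panel.n_variants), dtype=np.uint8)
    flat_anc = hap_anc.reshape(G, 2 * n)  # columns: (individual, hap) pairs in C order
    for g in range(G):
        lo, hi = panel.gene_regions[g]
        blocks_g = panel.gene_blocks(g)
        region = np.zeros((2 * n, hi - lo), dtype=np.uint8)
        for k in range(n_pops):
            sel = np.flatnonzero(flat_anc[g] == k)
            if sel.size == 0:
                continue
            col = 0
            for b in blocks_g:
                blo, bhi = panel.blocks[b]
                w = bhi - blo
                r = panel.rho[b, k]
                shared = rng.standard_normal((sel.size, 1))
                eps = rng.standard_normal((sel.size, w))
                z = np.sqrt(r) * shared + np.sqrt(1 - r) * eps
                region[sel, col : col + w] = ndtr(z) < panel.freq[blo:bhi, k]
                col += w
        haplotypes[:, :, lo:hi] = region.reshape(n, 2, hi - lo)

    covariates = pd.DataFrame(
        {
            "age": rng.uniform(8.0, 21.0, n),
            "sex": rng.integers(0, 2, n),
            "asthma": rng.integers(0, 2, n),
        }
    )
    cohort = AdmixedCohort(
        panel=panel,
        haplotypes=haplotypes,
        hap_ancestry=hap_anc,
        theta=theta,
        covariates=covariates,
        seed=int(seed),
    )
    cohort.validate()
    return cohort


@dataclass
class ExpressionDataset:
    """Gene-by-sample expression values with per-gene simulation truth.

    ``truth`` has one row per gene: scenario label, causal variant index
    and id, per-ancestry effect sizes (expression s.d. per allele), the
    residual variance and the true cis-h2 implied by the construction.
    """

    expr: np.ndarray  # (n_genes, n_individuals)
    truth: pd.DataFrame
    gene_ids: list[str]

    def validate(self, cohort: AdmixedCohort) -> None:
        causal = self.truth["causal_idx"].dropna()
        if len(causal) and (causal.min() < 0 or causal.max() >= cohort.n_variants):
            raise ValueError("causal variant ids must exist in the cohort")
        h2 = self.truth["true_h2"]
        if np.any(h2 < 0) or np.any(h2 > 1):
            # h2 = 1 only in the degenerate noiseless limit (sigma_e2 = 0)
            raise ValueError("true h2 must lie in [0, 1]")


def _pick_causal(
    panel: AncestralPanel,
    cohort: AdmixedCohort,
    g: int,
    scenario: str,
    high_pop: int,
    low_pop: int,
    rng: np.random.Generator,
    causal_pool: str = "common_both",
) -> int:
    """Choose a causal variant in gene g's region matching the scenario."""
    idx = panel.gene_variants(g)
    f = panel.freq[idx]
    common_high = (f[:, high_pop] >= 0.05) & (f[:, high_pop] <= 0.95)
    common_both = common_high & (f[:, low_pop] >= 0.05) & (f[:, low_pop] <= 0.95)
    if scenario == "tier1":
        cand = idx[(panel.private_pop[idx] == high_pop)]
        if cand.size == 0:
            # fall back to the largest frequency contrast in the region
            diff = f[:, high_pop] - f[:, low_pop]
            cand = idx[np.argsort(diff)[-1:]]
    else:
        pool = common_high if causal_pool == "common_high" else common_both
        cand = idx[pool]
        if cand.size == 0:
            maf_pool = np.minimum(f.mean(axis=1), 1 - f.mean(axis=1))
            cand = idx[np.argsort(maf_pool)[-1:]]
    return int(rng.choice(cand))


def simulate_expression(
    cohort: AdmixedCohort,
    panel: AncestralPanel,
    scenario_config: Mapping | Sequence[str],
    seed: int = 0,
) -> ExpressionDataset:
    """Simulate expression under labeled cis-eQTL scenarios.

    Expression for gene g is ``beta * dosage(causal) + covariate effects +
    Gaussian noise``. Scenario semantics:

    - ``null``: no genetic effect (beta = 0, true h2 = 0);
    - ``shared``: one causal variant common in all ancestries, identical
      effect on every haplotype background;
    - ``tier1``: the causal variant is common (freq >= 0.05) in the high
      ancestry and essentially absent (< 0.005) elsewhere;
    - ``tier2``: causal variant common in both contrasted ancestries;
      ancestry-asymmetric tagging is planted through the panel's LD (see
      ``rho_override``), the per-allele effect itself is shared;
    - ``tier3``: causal variant common in both, but the per-allele effect
      differs by ancestral background of the carrying haplotype
      (``beta_low = beta_high / tier3_ratio``).

    ``scenario_config`` is either a sequence of per-gene scenario labels or
    a mapping with keys ``scenarios`` (required), ``h2`` (target cis-h2,
    default 0.2), ``tier3_ratio`` (default 3.0), ``high_pop``/``low_pop``
    (default 0/1) and ``covariate_betas``.

    The effect size is set from the target h2 via the single-variant
    variance identity ``V_G = 2 p (1 - p) beta^2`` with p the cohort
    allele frequency of the causal variant and residual variance
    ``1 - h2``, so that ``true h2 = V_G / (V_G + sigma_e^2)``.
    """
    if isinstance(scenario_config, Mapping):
        cfg = dict(scenario_config)
        scenarios = list(cfg.pop("scenarios"))
    else:
        cfg = {}
        scenarios = list(scenario_config)
    if len(scenarios) != panel.n_genes:
        raise ValueError("need one scenario label per gene")
    bad = set(scenarios) - set(SCENARIOS)
    if bad:
        raise ValueError(f"unknown scenario labels: {sorted(bad)}")
    h2_target = cfg.pop("h2", 0.2)
    h2_per_gene = np.broadcast_to(np.asarray(h2_target, dtype=float), (panel.n_genes,))
    if np.any(h2_per_gene >= 1) or np.any(h2_per_gene < 0):
        raise ValueError("target h2 must lie in [0, 1)")
    tier3_ratio = float(cfg.pop("tier3_ratio", 3.0))
    high_pop = int(cfg.pop("high_pop", 0))
    low_pop = int(cfg.pop("low_pop", 1))
    covariate_betas = cfg.pop("covariate_betas", None) or {}
    causal_pool = str(cfg.pop("causal_pool", "common_both"))
    if causal_pool not in ("common_both", "common_high"):
        raise ValueError("causal_pool must be 'common_both' or 'common_high'")
    sigma_e2_override = cfg.pop("sigma_e2", None)
    if sigma_e2_override is not None:
        sigma_e2_override = np.broadcast_to(
            np.asarray(sigma_e2_override, dtype=float), (panel.n_genes,)
        )
        if np.any(sigma_e2_override < 0):
            raise ValueError("sigma_e2 must be non-negative")
    if cfg:
        raise ValueError(f"unknown scenario_config keys: {sorted(cfg)}")

    n = cohort.n_individuals
    rng = _rng(seed, "expression")
    expr = np.empty((panel.n_genes, n))
    rows = []
    for g, scen in enumerate(scenarios):
        h2 = float(h2_per_gene[g])
        sigma_e2 = 1.0 if scen == "null" else 1.0 - h2
        if sigma_e2_override is not None:
            sigma_e2 = float(sigma_e2_override[g])
        noise = rng.standard_normal(n) * np.sqrt(sigma_e2)
        cov_part = sum(
            b * cohort.covariates[name].to_numpy(dtype=float) for name, b in covariate_betas.items()
        )
        if scen == "null" or h2 == 0.0:
            genetic = np.zeros(n)
            causal = None
            beta_high = beta_low = 0.0
            true_h2 = 0.0
        else:
            causal = _pick_causal(panel, cohort, g, scen, high_pop, low_pop, rng, causal_pool)
            dose = cohort.dosage[:, causal]
            p = np.clip(dose.mean() / 2.0, 0.005, 0.995)
            beta = np.sqrt(h2 / (2 * p * (1 - p)))
            if scen == "tier3":
                beta_high, beta_low = beta, beta / tier3_ratio
                anc = cohort.hap_ancestry[g]  # (n, 2)
                alleles = cohort.haplotypes[:, :, causal]  # (n, 2)
                per_hap_beta = np.where(anc == high_pop, beta_high, beta_low)
                genetic = (alleles * per_hap_beta).sum(axis=1)
                v_g = float(np.var(genetic))
            else:
                beta_high = beta_low = beta
                genetic = beta * dose
                v_g = 2 * p * (1 - p) * beta**2
            true_h2 = v_g / (v_g + sigma_e2) if (v_g + sigma_e2) > 0 else 0.0
        expr[g] = genetic + cov_part + noise
        rows.append(
            {
                "gene_id": panel.gene_ids[g],
                "scenario": scen,
                "causal_idx": np.nan if causal is None else causal,
                "causal_id": None if causal is None else panel.variant_ids[causal],
                "beta_high": beta_high,
                "beta_low": beta_low,
                "sigma_e2": sigma_e2,
                "true_h2": true_h2,
            }
        )
    truth = pd.DataFrame(rows)
    ds = ExpressionDataset(expr=expr, truth=truth, gene_ids=list(panel.gene_ids))
    ds.validate(cohort)
    return ds


def simulate_gwas_sumstats(
    panel: AncestralPanel,
    truth: pd.DataFrame,
    alpha_per_gene: Sequence[float] | np.ndarray,
    n_gwas: int = 10_000,
    seed: int = 0,
    theta: Sequence[float] | np.ndarray | Callable = (1.0, 1.0, 1.0),
    high_pop: int = 0,
) -> tuple[pd.DataFrame, AdmixedCohort, np.ndarray]:
    """GWAS summary statistics for a trait mediated by gene expression.

    A fresh population of ``n_gwas`` individuals is simulated from the
    panel; the trait is ``sum_g alpha_g * G_g + N(0, 1)`` where ``G_g`` is
    gene g's genetic expression component under the recorded truth (tier-3
    genes use haplotype-ancestry-specific effects). Marginal per-variant
    OLS on the trait yields beta, se and z (alternate allele is the effect
    allele). Monomorphic variants are dropped.

    Returns the summary-statistic table, the simulated GWAS population
    (usable as an in-sample LD reference) and the trait vector.
    """
    if n_gwas < 100:
        raise ValueError("n_gwas must be >= 100")
    alpha = np.asarray(alpha_per_gene, dtype=float)
    if alpha.size != panel.n_genes:
        raise ValueError("need one alpha per gene")
    pop = simulate_admixed_genotypes(panel, n_gwas, theta=theta, seed=(int(seed) * 2 + 1) % (2**31))
    rng = _rng(seed, "gwas")

    y = rng.standard_normal(n_gwas)
    for g in range(panel.n_genes):
        if alpha[g] == 0:
            continue
        row = truth.iloc[g]
        if not np.isfinite(row["causal_idx"]):
            continue
        causal = int(row["causal_idx"])
        if row["beta_high"] != row["beta_low"]:
            anc = pop.hap_ancestry[g]
            alleles = pop.haplotypes[:, :, causal]
            per_hap = np.where(anc == high_pop, row["beta_high"], row["beta_low"])
            genetic = (alleles * per_hap).sum(axis=1)
        else:
            genetic = row["beta_high"] * pop.dosage[:, causal]
        y = y + alpha[g] * genetic

    X = pop.dosage
    xm = X.mean(axis=0)
    xc = X - xm
    ssx = (xc**2).sum(axis=0)
    poly = ssx > 0
    yc = y - y.mean()
    ssy = float(yc @ yc)
    beta = np.full(X.shape[1], np.nan)
    beta[poly] = (xc[:, poly].T @ yc) / ssx[poly]
    rss = ssy - beta[poly] ** 2 * ssx[poly]
    se = np.sqrt(np.maximum(rss, 1e-300) / (n_gwas - 2) / ssx[poly])
    z = beta[poly] / se
    out = pd.DataFrame(
        {
            "variant_id": np.asarray(panel.variant_ids)[poly],
            "effect_allele": panel.alt[poly],
            "other_allele": panel.ref[poly],
            "beta": beta[poly],
            "se": se,
            "z": z,
            "n": n_gwas,
        }
    )
    return out, pop, y
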