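# Methods

This note documents the models implemented in `admixqtl`, the defaults
that matter, what the synthetic cohort generator does and does not
emulate, and the design choices made where the design was genuinely open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic admixed cohorts

**Ancestral panel.** Variant frequencies follow the Balding–Nichols drift
model: a shared base frequency p ~ U(0.05, 0.95) per variant, and a
per-population frequency drawn from Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k).
F_k is the population's differentiation parameter; expected
heterozygosity scales with (1 − F_k), so a bottlenecked population is
modeled with a larger F (defaults in the examples: F = 0.05 for the
high-diversity population, 0.3–0.35 for the bottlenecked one, 0.15
otherwise; two populations simulated at F = 0.15 reproduce a Hudson-
estimator FST of ≈ 0.15, checked in the tests). A configurable fraction
of variants (default 5%, 8% in classifier benchmarks) is forced
population-private: frequency U(0.05, 0.2) in one host population and
U(0.0002, 0.002) elsewhere. The host frequency is capped at 0.2 so that
admixture leakage into a low-ancestry group (< 10% global ancestry,
averaging ~3%) keeps the variant below the MAF 0.01 "rare" threshold
there, which is what defines a tier-1-like architecture.

**Genotypes and ancestry.** Variants live in disjoint per-gene cis
regions (2 Mb apart) subdivided into LD blocks (default 20 variants).
For each gene and haplotype, a local ancestry is drawn from the
individual's global proportions θ; alleles within a block are generated
by an equicorrelated Gaussian copula at that ancestry's latent
correlation ρ, which preserves the marginal frequency exactly while
letting LD differ between ancestral backgrounds. Local ancestry is
simulated per gene (a single cis-block ancestry) rather than as
chromosome-length tracts because only ancestry at the TSS enters any
downstream analysis. Haplotypes and their ancestral origins are retained
on the cohort object so ancestry-dependent effects can be simulated
exactly. Covariates are age ~ U(8, 21) years and Bernoulli(0.5) sex and
asthma status, with zero effect on expression by default (configurable).

**Expression scenarios.** Expression is β·dosage(causal) + covariate
effects + Gaussian noise. The per-allele effect is set from the target
cis-h² via the single-variant identity V_G = 2p(1−p)β² with p the
cohort allele frequency and residual variance 1 − h², so the recorded
true h² equals V_G/(V_G + σ²_e). The effect-size scale is normal on the
standardized scale — a modeling choice, as the field has no canonical
eQTL effect-size distribution. Scenario labels: `shared` (causal common
everywhere, one β), `tier1` (causal from the population-private pool),
`tier2` (causal common in both contrasted ancestries with
ancestry-asymmetric tag LD planted via per-gene ρ overrides), `tier3`
(same causal variant, per-haplotype effect depending on the haplotype's
ancestral background, default ratio 3), `null` (β = 0). A
`causal_pool="common_high"` option draws causal variants from the
spectrum common in the high-diversity population only; this is the
realistic sampling for heterozygosity-mechanism experiments, since
bottlenecked populations have lost part of that spectrum. The
noiseless limit (σ²_e = 0, true h² = 1) is supported only as a
degenerate test case.

**GWAS traits.** A fresh population is simulated from the panel; the
trait is Σ_g α_g·G_g + N(0, 1) with G_g the gene's genetic expression
component under the recorded truth. Marginal per-variant OLS yields β,
se and z (alternate allele = effect allele); the simulated population
doubles as an in-sample LD reference for summary-statistic TWAS.

**What the generator does not emulate.** Realistic recombination maps and
tract-length distributions, phasing error, sequencing/quantification
noise, population structure beyond the admixture model, polygenic or
trans effects, covariate–expression confounding, and multiple causal
variants per gene (every scenario plants exactly one). Passing tests
therefore demonstrate correctness of the statistical machinery under a
single-causal, block-LD world, not robustness to all features of real
data.

## Heritability

Cis-kinships use allele-frequency standardized dosages,
K = ZZᵀ/m with z = (g − 2p)/√(2p(1−p)), restricted to MAF ≥ 0.01; the
LDAK-Thin variant first greedily removes one of each near-duplicate pair
(r² > 0.98 within 100 kb). REML is average-information with an EM
fallback on steps that fail to improve the restricted likelihood,
without a positivity constraint — per-gene estimates may be negative,
which keeps group medians unbiased; summaries use medians. For a single
kinship the problem is rotated into the kinship eigenbasis, making each
iteration O(n·p²); multi-component (MAF-bin) fits use dense algebra.
Convergence: relative restricted log-likelihood change < 1e-6, at most
100 iterations (tolerances are implementation choices; no published
default exists for this pipeline). The σ²_g = 0 test is a
likelihood-ratio test against the boundary null with the ½χ²₀ + ½χ²₁
mixture; LRT ≤ 0 reports p = 1. Group contrasts use a two-sided Wilcoxon
rank-sum with normal approximation and tie-corrected variance (a fully
tied comparison reports p = 1).

## Ancestry association

The stepwise cascade is implemented literally as stated rather than as a
joint mixed model: model 0 regresses rank-inverse-normalized expression
on age, sex and asthma; model 1 regresses those residuals on global
ancestry; model 2 regresses the model-1 residuals on the local ancestral
allele count (additive 0/1/2 coding). BH FDR is applied to the model-1
and model-2 p-values separately. Joint variance attribution reports
sequential sums of squares in both orders, which brackets each
component's unique contribution; near-collinear θ and local counts
(r² > 0.999) are flagged rather than inverted.

## cis-eQTL mapping

Expression is rank-inverse-normal transformed per gene (offset 0.5),
residualized on covariates, and then on the top principal components of
the covariate-residualized expression matrix. PCs stand in for a
Bayesian latent-factor correction: they are its point-estimate
approximation, keep the pipeline dependency-free, and default to 15
factors for cohorts of n ≤ 1000 (5 in the classification pipeline,
where the gene panel is small). The scan is simple per-variant OLS in
the ±1 Mb window (MAF ≥ 0.01), with two-sided p from t(n−2).

Gene-level calibration permutes the expression vector: the minimum
nominal p of each permutation is recorded; permutation stops early once
≥ 30 minima beat the observed minimum (and ≥ 100 permutations have run),
up to 1000. A Beta(a, b) is fit to the minima by Nelder–Mead maximum
likelihood from a method-of-moments start; the beta-approximated gene p
is the Beta CDF at the observed minimum (degenerate minima fall back to
the empirical p, flagged). eGenes are BH-significant at FDR 0.05; each
significant gene's nominal threshold inverts its fitted Beta at the
gene-level p of the FDR boundary (midpoint of the largest significant
and smallest non-significant gene p — the convention used by large eQTL
consortia). Clumping is greedy: best remaining variant becomes an index,
absorbing variants within 1 Mb at Pearson r² > 0.1 on mean-imputed
dosages.

## Fine-mapping and heterogeneity

Single-causal posteriors normalize Wakefield approximate Bayes factors,
√(se²/(se² + W))·exp(z²W/(2(se² + W))), computed in log space; the prior
effect s.d. is W^0.5 = 0.15 on the standardized scale (configurable —
deliberately skeptical relative to typical simulated effects, which
widens credible sets and makes their coverage conservative). se defaults
to 1/√n. Credible sets take the smallest PP-sorted prefix reaching the
level (0.95), with ties broken by genomic position for determinism.

The cross-population configuration posterior assumes at most one causal
variant per ancestry group: within a group the posterior over
configurations (no causal variant, or causal at variant j) is
proportional to prior × ABF, uniform over the M + 1 configurations by
default; groups are independent given the configuration, so
PP_shared(j) = P_high(j)·P_low(j), PP_high(j) = P_high(j)·(1 − P_low(j)),
and symmetrically. This replaces a genome-wide MCMC prior-estimation
step with fixed per-gene priors — a documented simplification: the tier
classifier consumes only the PP ordering and the 0.8 threshold. Before
computing it, variant pairs with r² > 0.95 in *both* groups are reduced
to one representative (kept by smallest high-group nominal p); pruned
variants inherit their representative's posteriors.

Cochran's Q for two groups is (β_h − β_l)²/(se_h² + se_l²) against
χ²(1). The β and se come from each group's marginal scan on its own
inverse-normalized residualized expression; marginal-effect comparisons
are confounded by sampling error when group sizes differ, which is why
the tier-3 threshold is Bonferroni-protected (0.05/n_gene, with n_gene
the number of genes reaching the overlapping-sets step).

## The tier classifier

For each eligible gene (by default every high-group eGene; heritability
and protein-coding eligibility can be supplied as flags to reproduce
either denominator): if the high- and low-group 95% credible sets do not
overlap, the gene is tier 1 when the lead (highest-PP) high-group
credible-set variant has MAF ≥ 0.01 in the high group and < 0.01 in the
low group (a strict mode checks all members); otherwise tier 2 when all
credible-set members have PP_high > PP_low and PP_high > PP_shared and
the best member exceeds 0.8. If the sets overlap, the gene is tier 3
when every credible-set member's Q p-value beats 0.05/n_gene, else
shared; genes failing everything are "none". A gene with no detectable
low-group signal (not an eGene there) cannot yield a low-group credible
set; it is classified through the high-group set alone and flagged
`low_group_silent` — the MAF rule decides tier 1, else the configuration
posterior decides tier 2.

Two behaviors of the benchmark are worth knowing. First, planted
"tier2" scenarios (causal observed and common in both groups, shared
effect, asymmetric tag LD) are usually called *shared*: both credible
sets contain the genotyped causal variant, so they overlap — correctly,
since the signal is shared. Tier-2 calls in practice arise from genes
whose low-group signal is undetectable. Second, planted "tier3"
scenarios with a strong effect ratio often present as tier 2 or none,
because the attenuated low-group effect falls below eGene detection at
group sizes of a few hundred; detected heterogeneity at the Bonferroni
threshold is rare, consistent with effect-size heterogeneity being the
rarest anc-eQTL class.

## TWAS

Per-gene elastic-net models (mixing 0.5, the PredictDB convention;
penalty path of 25 values chosen by inner 5-fold CV) are evaluated by
10-fold outer cross-validation: rho_avg is the mean fold Pearson
correlation between out-of-fold predictions and observations, and
zscore_pval the one-sided p of mean(ρ)√K/sd(ρ). Fold counts are
conventions (flagged in the configuration), not published values.
Models pass the filters when rho_avg > 0.1, zscore_pval < 0.05 and the
gene's heritability LRT p < 0.05. An optional local-ancestry covariate
mode residualizes ancestral allele counts out of expression before
training. Weights are stored as flat tables (gene, variant, alleles,
weight) for transparency. The summary-statistic association is
z_gene = Σ_l w_l (σ_l/σ_g) z_l with σ²_g = wᵀΓw from an LD reference;
model variants are matched to the GWAS by id with sign flips on
swapped alleles and mismatched alleles dropped.

## Numerical choices and degenerate inputs

- Constant predictors (zero-variance dosages, constant θ or local
  counts) yield per-gene NA or are skipped, never raised mid-pipeline;
  constant expression is flagged.
- Monomorphic-only cis windows raise an explicit "no informative
  variants" error from kinship construction.
- An identity kinship (unidentifiable model) converges to a boundary fit
  with LRT p = 1 rather than erroring.
- Posterior normalizations use log-sum-exp; z-scores of ±100+ are safe.
- All generators derive their streams from one integer seed via named
  substreams, so every artifact is a pure function of (config, seed).

## Problem sizes

Validation experiments run at desk scale: 500 regions × 200 variants ×
n = 600 for credible-set coverage; 200 genes × n = 600 for heritability
recovery and directional contrasts; 100 genes per scenario × n = 600 for
the classifier benchmark; 50 genes × 10,000 permutations for the beta
approximation check; 100 genes × n = 400 training with GWAS n in the
thousands for TWAS. These sizes give Monte-Carlo error comfortably
inside each check's tolerance.

## Known limitations

- The single-causal assumption is baked into both the fine-mapping and
  the generator; genes with multiple independent signals would dilute
  credible-set overlap logic.
- The configuration posterior's fixed uniform priors ignore genome-wide
  information a full cross-population fine-mapper would estimate.
- Group-specific scans re-standardize expression within groups, so
  cross-group β comparisons are on per-group standardized scales; Q
  tests inherit that caveat.
- LD is block-equicorrelated; real decay patterns, long-range admixture
  LD and negative LD are absent.
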