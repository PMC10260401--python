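"""Simulate an admixed cohort with labeled cis-eQTL scenarios and write it out.

Builds a three-population ancestral panel (a high-diversity population, a
bottlenecked one, and an intermediate one), draws 400 admixed individuals,
simulates expression for 10 genes under labeled scenarios, and writes
VCF / BED / TSV files to ./scratch/example_cohort.
"""

import numpy as np

import admixqtl as aq
from admixqtl import io

panel = aq.simulate_ancestral_panel(
    n_pops=3,
    n_variants=1000,
    n_genes=10,
    block_size=20,
    rho_per_pop=0.5,
    F=(0.05, 0.3, 0.15),  # pop 0 high-diversity, pop 1 bottlenecked
    seed=1,
    private_fraction=0.08,
    pop_labels=["AFR", "IAM", "EUR"],
)
theta = aq.two_group_theta(400, 3, focal_pop=0, seed=2)
cohort = aq.simulate_admixed_genotypes(panel, 400, theta=theta, seed=3)
scenarios = ["tier1", "tier1", "shared", "shared", "tier3", "tier2", "null", "null", "shared", "tier1"]
expr = aq.simulate_expression(cohort, panel, {"scenarios": scenarios, "h2": 0.2}, seed=4)

print(f"cohort: {cohort.n_individuals} individuals, {cohort.n_variants} variants, {panel.n_genes} genes")
print(f"mean global ancestry (AFR, IAM, EUR): {np.round(cohort.theta.mean(axis=0), 3)}")
print("\nper-gene simulation truth:")
print(expr.truth[["gene_id", "scenario", "causal_id", "beta_high", "true_h2"]].to_string(index=False))

paths = io.write_cohort(cohort, expr, "scratch/example_cohort")
print("\nwrote:", *[str(p) for p in paths.values()], sep="\n  ")
# Each truth row records the planted causal variant, its per-ancestry effect
# (expression s.d. per allele) and the cis-h2 implied by the construction.
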