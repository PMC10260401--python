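"""Classify ancestry-specific eQTLs with the tier decision tree.

Simulates 50 genes across labeled scenarios, runs the full high- vs
low-ancestry contrast (scans, permutation calibration, credible sets,
cross-population posteriors, Cochran's Q), and prints the calls against
the planted truth plus the prevalence summary.
"""

import pandas as pd

import admixqtl as aq
from admixqtl import classify, pipeline

scen = ["tier1"] * 15 + ["shared"] * 15 + ["tier3"] * 10 + ["null"] * 10
G = len(scen)
panel = aq.simulate_ancestral_panel(
    n_pops=3, n_variants=100 * G, n_genes=G, block_size=20,
    rho_per_pop=0.5, F=(0.05, 0.3, 0.15), seed=31, private_fraction=0.08,
    pop_labels=["AFR", "IAM", "EUR"],
)
theta = aq.two_group_theta(600, 3, focal_pop=0, seed=32)
cohort = aq.simulate_admixed_genotypes(panel, 600, theta=theta, seed=33)
expr = aq.simulate_expression(cohort, panel, {"scenarios": scen, "h2": 0.15}, seed=34)

res = pipeline.run_contrast(cohort, expr, focal_pop=0, seed=35)
df = res.calls_df.merge(expr.truth[["gene_id", "scenario"]], on="gene_id")

print("confusion matrix (rows = planted scenario, columns = call):")
print(pd.crosstab(df.scenario, df.call))
print(f"\ngenes reaching the overlapping-sets step (tier-3 Bonferroni n_gene): {res.n_gene_tier3}")
print("\nprevalence among classified genes:")
print(classify.prevalence(res.calls, list(df.gene_id)).to_string(index=False))
print("\ntier 1 = allele-frequency driven (common only in the high-ancestry group);")
print("tier 2 = LD-driven, cross-population posterior specific to the high group;")
print("tier 3 = shared signal with significant effect-size heterogeneity.")
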