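"""Estimate cis-heritability by REML and contrast ancestry groups.

Simulates 60 genes with shared effect sizes in a cohort admixed between a
high-diversity and a bottlenecked ancestry, fits unconstrained REML per
gene within the high (> 50%) and low (< 10%) focal-ancestry groups, and
compares the h2 and V_G distributions with a Wilcoxon rank-sum test —
the heterozygosity mechanism predicts higher values in the high group.
"""

import numpy as np

import admixqtl as aq
from admixqtl import heritability as her

G, n = 60, 500
panel = aq.simulate_ancestral_panel(
    n_pops=2, n_variants=60 * G, n_genes=G, F=(0.05, 0.35), seed=11, private_fraction=0.05
)
theta = aq.two_group_theta(n, 2, focal_pop=0, seed=12)
cohort = aq.simulate_admixed_genotypes(panel, n, theta=theta, seed=13)
expr = aq.simulate_expression(
    cohort, panel, {"scenarios": ["shared"] * G, "h2": 0.3, "causal_pool": "common_high"}, seed=14
)

hi = np.flatnonzero(theta[:, 0] > 0.5)
lo = np.flatnonzero(theta[:, 0] < 0.1)
h2 = {"high": [], "low": []}
vg = {"high": [], "low": []}
for g in range(G):
    win = panel.gene_variants(g)
    for tag, idx in (("high", hi), ("low", lo)):
        K = her.build_kinship(cohort.dosage[np.ix_(idx, win)])
        fit = aq.reml_fit(K, expr.expr[g][idx])
        h2[tag].append(fit.h2)
        vg[tag].append(fit.V_G)

t_h2 = aq.compare_groups(h2["high"], h2["low"])
t_vg = aq.compare_groups(vg["high"], vg["low"])
print(f"median h2-hat: high-ancestry group {t_h2.median_a:.3f} vs low {t_h2.median_b:.3f} "
      f"(two-sided Wilcoxon p = {t_h2.p:.2e})")
print(f"median V_G-hat: high-ancestry group {t_vg.median_a:.3f} vs low {t_vg.median_b:.3f} "
      f"(two-sided Wilcoxon p = {t_vg.p:.2e})")
print("\nA higher median in the high-diversity group reflects greater causal-variant")
print("heterozygosity (V_G = 2p(1-p)beta^2) under identical per-allele effects.")
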