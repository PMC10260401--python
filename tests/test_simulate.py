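"""Generator correctness: drift model, admixture, LD, scenario truth, GWAS."""

import numpy as np
import pytest

import admixqtl as aq
from admixqtl.simulate import simulate_ancestral_panel


def hudson_fst(p1, p2, n1, n2):
    """Independent Hudson-estimator oracle on per-population sample frequencies."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.sum() / den.sum()


class TestAncestralPanel:
    def test_determinism_and_invariants(self, small_panel):
        again = simulate_ancestral_panel(
            n_pops=3, n_variants=600, n_genes=6, block_size=10,
            rho_per_pop=0.5, F=(0.05, 0.3, 0.15), seed=101, private_fraction=0.08,
        )
        assert np.array_equal(small_panel.freq, again.freq)
        assert np.array_equal(small_panel.positions, again.positions)
        small_panel.validate()  # block partition, [0,1] freqs, increasing positions

    def test_divergence_free_limit(self):
        panel = simulate_ancestral_panel(
            n_pops=3, n_variants=2000, n_genes=2, F=1e-6, seed=7, private_fraction=0.0
        )
        spread = panel.freq.max(axis=1) - panel.freq.min(axis=1)
        assert spread.max() < 0.01

    def test_fst_matches_hudson_oracle(self, rng):
        panel = simulate_ancestral_panel(
            n_pops=2, n_variants=10_000, n_genes=5, F=0.15, seed=31, private_fraction=0.0
        )
        n_hap = 10_000
        counts = rng.binomial(n_hap, panel.freq)  # sampled haplotypes per population
        p = counts / n_hap
        fst = hudson_fst(p[:, 0], p[:, 1], n_hap, n_hap)
        assert fst == pytest.approx(0.15, abs=0.02)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_ancestral_panel(F=1.5, seed=0)
        with pytest.raises(ValueError):
            simulate_ancestral_panel(rho_per_pop=1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_ancestral_panel(n_pops=1, seed=0)


class TestAdmixedGenotypes:
    def test_cohort_invariants(self, small_cohort):
        small_cohort.validate()  # theta sums, local-ancestry sums, dosage range

    def test_pure_ancestry_limit(self, small_panel):
        coh = aq.simulate_admixed_genotypes(small_panel, 50, theta=(1.0, 0.0, 0.0), seed=5)
        assert np.all(coh.local_anc[:, :, 0] == 2)

    def test_local_ancestry_binomial_mean(self, small_panel):
        theta = np.tile([0.8, 0.1, 0.1], (1000, 1))
        coh = aq.simulate_admixed_genotypes(small_panel, 1000, theta=theta, seed=6)
        mean_counts = coh.local_anc[:, :, 0].mean(axis=1)  # per gene
        assert np.all(np.abs(mean_counts - 1.6) < 0.05)

    def test_frequency_preservation_no_ld(self, small_panel):
        import copy

        panel = copy.deepcopy(small_panel)
        panel.freq[:] = 0.5
        panel.rho[:] = 0.0
        coh = aq.simulate_admixed_genotypes(panel, 1000, theta=(1.0, 1.0, 1.0), seed=8)
        maf = coh.maf()
        assert np.abs(maf - 0.5).max() < 0.06
        # unfolded frequency is unbiased (the folded MAF is biased down by E|p_hat - 0.5|)
        assert np.abs(coh.sample_freq().mean() - 0.5) < 0.005

    def test_too_few_individuals(self, small_panel):
        with pytest.raises(ValueError):
            aq.simulate_admixed_genotypes(small_panel, 1, seed=0)

    def test_determinism(self, small_panel):
        a = aq.simulate_admixed_genotypes(small_panel, 40, theta=(1.0, 1.0, 1.0), seed=9)
        b = aq.simulate_admixed_genotypes(small_panel, 40, theta=(1.0, 1.0, 1.0), seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.theta, b.theta)

    def test_block_ld_increases_with_rho(self):
        freqs = {}
        for rho in (0.0, 0.8):
            panel = simulate_ancestral_panel(
                n_pops=2, n_variants=200, n_genes=1, block_size=10,
                rho_per_pop=rho, F=0.1, seed=77, private_fraction=0.0,
            )
            coh = aq.simulate_admixed_genotypes(panel, 500, theta=(1.0, 0.0), seed=78)
            X = coh.dosage[:, :10]
            r = np.corrcoef(X.T)
            freqs[rho] = np.abs(r[np.triu_indices(10, 1)]).mean()
        assert freqs[0.8] > freqs[0.0] + 0.2


class TestExpressionScenarios:
    def test_null_scenario(self, small_panel, small_cohort, small_expression):
        g = list(small_expression.truth.scenario).index("null")
        assert small_expression.truth.true_h2[g] == 0.0
        win = small_panel.gene_variants(g)
        X = small_cohort.dosage[:, win]
        ok = X.std(axis=0) > 0
        r = np.array([np.corrcoef(X[:, j], small_expression.expr[g])[0, 1] for j in np.flatnonzero(ok)])
        assert np.abs(r).max() < 0.25  # no systematic cis signal

    def test_analytic_genetic_variance(self):
        panel = simulate_ancestral_panel(
            n_pops=2, n_variants=100, n_genes=1, F=0.05, seed=41, private_fraction=0.0
        )
        coh = aq.simulate_admixed_genotypes(panel, 5000, theta=(1.0, 0.0), seed=42)
        ds = aq.simulate_expression(coh, panel, {"scenarios": ["shared"], "h2": 0.1}, seed=43)
        causal = int(ds.truth.causal_idx[0])
        genetic = ds.truth.beta_high[0] * coh.dosage[:, causal]
        assert np.var(genetic) == pytest.approx(0.1, abs=0.01)
        assert ds.truth.true_h2[0] == pytest.approx(0.1, abs=0.01)

    def test_noiseless_limit_exact_affine(self, small_panel, small_cohort):
        ds = aq.simulate_expression(
            small_cohort, small_panel,
            {"scenarios": ["shared"] * 6, "h2": 0.5, "sigma_e2": 0.0},
            seed=44,
        )
        causal = int(ds.truth.causal_idx[0])
        r = np.corrcoef(small_cohort.dosage[:, causal], ds.expr[0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_h2_bounds_raise(self, small_panel, small_cohort):
        with pytest.raises(ValueError):
            aq.simulate_expression(small_cohort, small_panel, {"scenarios": ["shared"] * 6, "h2": 1.0})

    def test_truth_labels_and_causals_exist(self, small_expression, small_cohort):
        small_expression.validate(small_cohort)
        assert set(small_expression.truth.scenario) <= set(aq.simulate.SCENARIOS)

    def test_tier1_causal_is_ancestry_private(self, small_panel, small_cohort, small_expression):
        row = small_expression.truth[small_expression.truth.scenario == "tier1"].iloc[0]
        causal = int(row.causal_idx)
        f = small_panel.freq[causal]
        assert f[0] >= 0.05 and f[1] < 0.01 and f[2] < 0.01

    def test_vg_monotone_in_heterozygosity(self):
        # fixed beta: V_G = 2 p (1 - p) beta^2 grows with heterozygosity
        panel = simulate_ancestral_panel(
            n_pops=2, n_variants=30, n_genes=1, F=0.05, seed=51, private_fraction=0.0
        )
        import copy

        beta = 0.5
        medians = []
        for p in (0.05, 0.2, 0.5):
            pan = copy.deepcopy(panel)
            pan.freq[:] = p
            coh = aq.simulate_admixed_genotypes(pan, 2000, theta=(1.0, 0.0), seed=52)
            vg = [np.var(beta * coh.dosage[:, j]) for j in range(30)]
            medians.append(np.median(vg))
        assert medians[0] < medians[1] < medians[2]


class TestGwasSumstats:
    def test_null_z_calibration(self):
        panel = simulate_ancestral_panel(
            n_pops=2, n_variants=5000, n_genes=5, F=0.1, seed=61,
            private_fraction=0.0, rho_per_pop=0.0,  # independent variants
        )
        coh = aq.simulate_admixed_genotypes(panel, 300, theta=(1.0, 1.0), seed=62)
        ds = aq.simulate_expression(coh, panel, {"scenarios": ["null"] * 5}, seed=63)
        ss, _, _ = aq.simulate_gwas_sumstats(panel, ds.truth, np.zeros(5), n_gwas=500, seed=64, theta=(1.0, 1.0))
        assert len(ss) >= 5000 - 50
        assert abs(ss.z.mean()) < 0.05
        assert abs(ss.z.var() - 1.0) < 0.1
        # z consistent with beta/se
        assert np.allclose(ss.z, ss.beta / ss.se, atol=1e-8)

    def test_mediating_gene_top_hit_power(self):
        hits = 0
        reps = 40
        for rep in range(reps):
            panel = simulate_ancestral_panel(
                n_pops=2, n_variants=100, n_genes=1, F=0.1, seed=700 + rep, private_fraction=0.0
            )
            coh = aq.simulate_admixed_genotypes(panel, 200, theta=(1.0, 1.0), seed=701 + rep)
            ds = aq.simulate_expression(coh, panel, {"scenarios": ["shared"], "h2": 0.3}, seed=702 + rep)
            ss, _, _ = aq.simulate_gwas_sumstats(
                panel, ds.truth, [0.3], n_gwas=10_000, seed=703 + rep, theta=(1.0, 1.0)
            )
            causal_id = ds.truth.causal_id[0]
            if ss.loc[ss.z.abs().idxmax(), "variant_id"] == causal_id:
                hits += 1
        assert hits / reps >= 0.9

    def test_determinism(self, small_panel, small_expression):
        alpha = np.zeros(6)
        a, _, _ = aq.simulate_gwas_sumstats(small_panel, small_expression.truth, alpha, 200, seed=9)
        b, _, _ = aq.simulate_gwas_sumstats(small_panel, small_expression.truth, alpha, 200, seed=9)
        assert a.equals(b)

    def test_small_n_raises(self, small_panel, small_expression):
        with pytest.raises(ValueError):
            aq.simulate_gwas_sumstats(small_panel, small_expression.truth, np.zeros(6), n_gwas=50, seed=1)
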