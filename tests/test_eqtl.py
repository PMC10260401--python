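"""Cis scans, permutation/beta calibration, eGene FDR and LD clumping."""

import numpy as np
import pytest
from scipy import stats

import admixqtl as aq
from admixqtl import eqtl


class TestPrepareExpression:
    def test_zero_factors_equals_covariate_residuals(self, rng):
        expr = rng.standard_normal((5, 100))
        cov = rng.standard_normal((100, 3))
        out = eqtl.prepare_expression(expr, cov, n_hidden_factors=0)
        X = np.column_stack([np.ones(100), cov])
        H = X @ np.linalg.pinv(X)
        for g in range(5):
            y = aq.ancestry.inverse_normal_transform(expr[g])
            assert np.allclose(out[g], y - H @ y, atol=1e-10)

    def test_planted_batch_factor_removed(self, rng):
        G, n = 40, 200
        expr = rng.standard_normal((G, n))
        batch = rng.standard_normal(n)
        expr += 2.0 * batch  # the same shift hits every gene
        before = np.corrcoef(expr)[np.triu_indices(G, 1)].mean()
        out = eqtl.prepare_expression(expr, None, n_hidden_factors=1)
        after = np.corrcoef(out)[np.triu_indices(G, 1)].mean()
        assert before > 0.5
        assert abs(after) < 0.05

    def test_rank_preservation(self, rng):
        expr = rng.standard_normal((1, 50))
        out = eqtl.prepare_expression(expr, None, n_hidden_factors=0)
        assert np.array_equal(np.argsort(out[0]), np.argsort(expr[0]))

    def test_too_many_factors_raise(self, rng):
        with pytest.raises(ValueError):
            eqtl.prepare_expression(rng.standard_normal((5, 40)), None, n_hidden_factors=20)


class TestCisScan:
    def test_closed_form_oracle(self):
        # 6-sample hand dataset checked against explicit normal equations
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        y = np.array([0.3, 1.1, 1.8, 0.2, 1.4, 2.2])
        scan = eqtl.cis_scan("g", x[:, None], y, maf_min=0.0)
        n = 6
        xc, yc = x - x.mean(), y - y.mean()
        beta = (xc @ yc) / (xc @ xc)
        rss = yc @ yc - beta**2 * (xc @ xc)
        se = np.sqrt(rss / (n - 2) / (xc @ xc))
        t = beta / se
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert scan.beta[0] == pytest.approx(beta, abs=1e-10)
        assert scan.se[0] == pytest.approx(se, abs=1e-10)
        assert scan.t[0] == pytest.approx(t, abs=1e-10)
        assert scan.p[0] == pytest.approx(p, abs=1e-10)

    def test_perfect_signal_wins_window(self, small_cohort):
        win = small_cohort.panel.gene_variants(0)
        X = small_cohort.dosage[:, win]
        j = 7
        y = X[:, j].copy()
        scan = eqtl.cis_scan("g", X, y, maf_min=0.01)
        best_global = scan.variant_idx[scan.best]
        assert best_global == j or np.allclose(X[:, best_global], X[:, j])
        assert scan.beta[scan.best] == pytest.approx(1.0, abs=1e-8)

    def test_null_p_uniform(self, rng):
        n, m = 150, 2000
        X = rng.binomial(2, 0.4, (n, m)).astype(float)
        y = rng.standard_normal(n)
        scan = eqtl.cis_scan("g", X, y, maf_min=0.0)
        assert stats.kstest(scan.p, "uniform").pvalue > 0.01

    def test_zero_variance_skipped(self, rng):
        X = np.column_stack([np.full(50, 2.0), rng.binomial(2, 0.5, 50).astype(float)])
        scan = eqtl.cis_scan("g", X, rng.standard_normal(50), maf_min=0.0)
        assert 0 in scan.skipped and scan.variant_idx.tolist() == [1]

    def test_sample_order_invariance(self, rng):
        n, m = 80, 30
        X = rng.binomial(2, 0.3, (n, m)).astype(float)
        y = rng.standard_normal(n)
        perm = rng.permutation(n)
        a = eqtl.cis_scan("g", X, y)
        b = eqtl.cis_scan("g", X[perm], y[perm])
        assert np.allclose(a.p, b.p, atol=1e-12)


class TestPermutationCalibration:
    def test_order_statistic_beta_shape(self, rng):
        # min of M independent uniforms is Beta(1, M): fitted (a, b) near (1, M)
        n, M = 300, 50
        X = rng.binomial(2, rng.uniform(0.2, 0.8, M), (n, M)).astype(float)
        y = rng.standard_normal(n)
        cal = eqtl.permute_calibrate("g", y, X, max_permutations=1000, seed=5,
                                     early_stop_hits=10**9)
        assert cal.beta_a == pytest.approx(1.0, rel=0.2)
        assert cal.beta_b == pytest.approx(M, rel=0.2)

    def test_null_gene_large_p(self, rng):
        n = 100
        x = rng.binomial(2, 0.5, n).astype(float)
        y = x - x.mean()
        y = rng.standard_normal(n)
        y -= (y @ (x - x.mean())) / ((x - x.mean()) @ (x - x.mean())) * (x - x.mean())  # r = 0
        cal = eqtl.permute_calibrate("g", y, x[:, None], max_permutations=200, seed=6)
        assert cal.p_empirical > 0.97
        assert cal.degenerate or cal.p_beta > 0.5

    def test_monotone_in_observed_p(self, rng):
        n, M = 200, 40
        X = rng.binomial(2, 0.4, (n, M)).astype(float)
        y0 = rng.standard_normal(n)
        y1 = y0 + 0.4 * X[:, 0]
        cal0 = eqtl.permute_calibrate("g", y0, X, seed=7, early_stop_hits=10**9)
        cal1 = eqtl.permute_calibrate("g", y1, X, seed=7, early_stop_hits=10**9)
        assert cal1.p_nominal_min < cal0.p_nominal_min
        assert cal1.p_beta < cal0.p_beta

    def test_determinism(self, rng):
        n, M = 120, 20
        X = rng.binomial(2, 0.4, (n, M)).astype(float)
        y = rng.standard_normal(n)
        a = eqtl.permute_calibrate("g", y, X, seed=11)
        b = eqtl.permute_calibrate("g", y, X, seed=11)
        assert a.p_beta == b.p_beta and a.n_permutations == b.n_permutations


class TestEgeneFdr:
    def _cal(self, gid, p, a=1.0, b=50.0):
        return eqtl.PermutationCalibration(
            gene_id=gid, n_permutations=1000, beta_a=a, beta_b=b,
            p_beta=p, p_empirical=p, p_nominal_min=stats.beta.ppf(p, a, b),
            degenerate=False,
        )

    def test_bh_step_up_hand_enumeration(self):
        # sorted p (0.001, 0.02, 0.9); BH thresholds (0.05/3, 0.1/3, 0.05):
        # k = 2 passes (0.02 <= 0.0333), so exactly two eGenes
        cals = [self._cal("g1", 0.001), self._cal("g2", 0.02), self._cal("g3", 0.9)]
        res = eqtl.egene_fdr(cals, fdr=0.05)
        assert res.is_egene.sum() == 2
        assert set(res[res.is_egene].gene_id) == {"g1", "g2"}

    def test_global_null_no_egenes(self):
        cals = [self._cal(f"g{i}", 1.0) for i in range(10)]
        res = eqtl.egene_fdr(cals)
        assert res.is_egene.sum() == 0
        assert res.nominal_threshold.isna().all()

    def test_input_order_invariance_with_duplicates(self):
        ps = [0.01, 0.5, 0.01, 0.2]
        cals = [self._cal(f"g{i}", p) for i, p in enumerate(ps)]
        a = eqtl.egene_fdr(list(cals))
        b = eqtl.egene_fdr(list(reversed(cals)))
        assert a.sort_values("gene_id").reset_index(drop=True).equals(
            b.sort_values("gene_id").reset_index(drop=True)
        )

    def test_threshold_inverts_beta_at_boundary(self):
        cals = [self._cal("g1", 0.001), self._cal("g2", 0.9)]
        res = eqtl.egene_fdr(cals, fdr=0.05)
        boundary = (0.001 + 0.9) / 2
        expected = stats.beta.ppf(boundary, 1.0, 50.0)
        got = res.loc[res.gene_id == "g1", "nominal_threshold"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-10)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            eqtl.egene_fdr([])


class TestClump:
    def test_perfect_ld_single_clump(self, rng):
        x = rng.binomial(2, 0.5, 100).astype(float)
        X = np.tile(x[:, None], (1, 5))
        assign = eqtl.clump(np.linspace(0.001, 0.01, 5), X, np.arange(5) * 100)
        assert len(set(assign)) == 1

    def test_no_ld_one_clump_each(self, rng):
        X = rng.binomial(2, 0.5, (2000, 6)).astype(float)
        p = np.linspace(0.001, 0.01, 6)
        assign = eqtl.clump(p, X, np.arange(6) * 100, r2_max=0.1)
        assert len(set(assign)) == 6

    def test_matches_bruteforce_greedy_oracle(self, rng):
        n, m = 300, 10
        base = rng.binomial(2, 0.5, (n, 3)).astype(float)
        X = np.column_stack([base[:, i % 3] for i in range(m)]) + rng.normal(0, 0.4, (n, m))
        p = rng.uniform(0, 1, m)
        pos = np.sort(rng.choice(10**6, m, replace=False))
        assign = eqtl.clump(p, X, pos, r2_max=0.1, window_kb=1000)

        # independent greedy replay
        r = np.corrcoef(X.T)
        free = set(range(m))
        expected = np.full(m, -1)
        for j in np.argsort(p, kind="stable"):
            if j not in free:
                continue
            expected[j] = j
            free.discard(j)
            for k in sorted(free):
                if abs(int(pos[k]) - int(pos[j])) <= 10**6 and r[j, k] ** 2 > 0.1:
                    expected[k] = j
                    free.discard(k)
        assert np.array_equal(assign, expected)

    def test_window_limits_clumping(self, rng):
        x = rng.binomial(2, 0.5, 200).astype(float)
        X = np.tile(x[:, None], (1, 2))
        assign = eqtl.clump(np.array([0.001, 0.002]), X, np.array([0, 2 * 10**6]))
        assert len(set(assign)) == 2  # identical variants, but 2 Mb apart


class TestEgeneNullFdrSmall:
    def test_null_fraction_controlled(self, rng):
        # quick global-null check (the full 500-gene version is an acceptance test)
        G, n, M = 60, 120, 30
        cals = []
        for g in range(G):
            X = rng.binomial(2, 0.4, (n, M)).astype(float)
            y = rng.standard_normal(n)
            cals.append(eqtl.permute_calibrate(f"g{g}", y, X, max_permutations=300, seed=100 + g))
        res = eqtl.egene_fdr(cals, fdr=0.05)
        assert res.is_egene.mean() <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / G)
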