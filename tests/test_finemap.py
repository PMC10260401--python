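"""Single-causal posteriors, credible sets, configuration posteriors, Cochran's Q."""

import numpy as np
import pytest
from scipy import stats

from admixqtl import finemap


def direct_abf_posterior(z, se, W):
    """Independent oracle: unnormalized Wakefield ABFs computed directly."""
    bf = np.sqrt(se**2 / (se**2 + W)) * np.exp(z**2 * W / (2 * (se**2 + W)))
    return bf / bf.sum()


class TestSingleCausalPosterior:
    def test_matches_direct_abf_oracle(self):
        z = np.array([4.0, 3.0, 2.0, 1.0, 0.0])
        n = 500
        se = np.full(5, 1 / np.sqrt(n))
        pp = finemap.single_causal_posterior(z, sample_size=n, prior_sd=0.15)
        assert np.allclose(pp, direct_abf_posterior(z, se, 0.15**2), atol=1e-10)
        assert pp.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dominant_signal(self):
        z = np.zeros(50)
        z[13] = 10.0
        pp = finemap.single_causal_posterior(z, sample_size=400)
        assert pp[13] > 0.999

    def test_perfect_ld_symmetry(self):
        pp = finemap.single_causal_posterior(np.array([6.0, 6.0]), sample_size=300)
        assert np.allclose(pp, 0.5)

    def test_top_variant_is_max_abs_z(self, rng):
        z = rng.standard_normal(100) * 2
        pp = finemap.single_causal_posterior(z, sample_size=500)
        assert np.argmax(pp) == np.argmax(np.abs(z))

    def test_overflow_safe_large_z(self):
        pp = finemap.single_causal_posterior(np.array([120.0, 0.0]), sample_size=10_000)
        assert np.isfinite(pp).all() and pp[0] > 0.999999


class TestCredibleSet:
    def test_single_member(self):
        cs = finemap.credible_set(np.array([0.97, 0.03]))
        assert cs.members.tolist() == [0]

    def test_uniform_has_95_members(self):
        cs = finemap.credible_set(np.full(100, 0.01), positions=np.arange(100))
        assert cs.members.size == 95
        # position tie-break keeps the lowest positions
        assert set(cs.members.tolist()) == set(range(95))

    def test_minimal_prefix_property(self, rng):
        for _ in range(20):
            pp = rng.dirichlet(np.ones(30))
            cs = finemap.credible_set(pp, level=0.95)
            assert cs.cumulative >= 0.95
            # removing the weakest member drops below the level (minimality)
            assert cs.cumulative - cs.pp[-1] < 0.95
            # oracle: smallest prefix of the sorted order
            srt = np.sort(pp)[::-1]
            k = int(np.searchsorted(np.cumsum(srt), 0.95 - 1e-12) + 1)
            assert cs.members.size == min(k, 30)

    def test_level_validation_and_sum_check(self):
        with pytest.raises(ValueError):
            finemap.credible_set(np.array([1.0]), level=1.5)
        with pytest.raises(ValueError):
            finemap.credible_set(np.array([0.4, 0.4]))

    def test_overlap(self):
        a = finemap.credible_set(np.array([0.5, 0.4, 0.1]))
        b = finemap.credible_set(np.array([0.96, 0.02, 0.02]))
        assert finemap.credible_sets_overlap(a, a)
        assert finemap.credible_sets_overlap(a, b)  # share variant 0
        c = finemap.CredibleSet(members=np.array([7]), pp=np.array([1.0]), level=0.95, cumulative=1.0)
        assert not finemap.credible_sets_overlap(b, c)


class TestConfigPosterior:
    def test_matches_exhaustive_configuration_oracle(self):
        z_h = np.array([5.0, 2.0, 0.5])
        z_l = np.array([1.0, 4.0, 0.2])
        n_h, n_l, W = 400, 350, 0.15**2
        cp = finemap.config_posterior(z_h, z_l, n_high=n_h, n_low=n_l)

        # brute force over all single-causal configurations in each group:
        # group configs are (none, v0, v1, v2); joint prob factorizes
        def weights(z, n):
            se = 1 / np.sqrt(n)
            bf = np.sqrt(se**2 / (se**2 + W)) * np.exp(z**2 * W / (2 * (se**2 + W)))
            w = np.concatenate([[1.0], bf]) / 4.0  # uniform prior over 4 configs
            return w / w.sum()

        wh, wl = weights(z_h, n_h), weights(z_l, n_l)
        joint = np.outer(wh, wl)
        for j in range(3):
            pp_shared = joint[j + 1, j + 1]
            pp_high = joint[j + 1].sum() - joint[j + 1, j + 1]
            pp_low = joint[:, j + 1].sum() - joint[j + 1, j + 1]
            assert cp.pp_shared[j] == pytest.approx(pp_shared, abs=1e-12)
            assert cp.pp_high[j] == pytest.approx(pp_high, abs=1e-12)
            assert cp.pp_low[j] == pytest.approx(pp_low, abs=1e-12)

    def test_one_sided_signal(self):
        z_h = np.concatenate([[8.0], np.zeros(19)])
        z_l = np.full(20, 0.1)
        cp = finemap.config_posterior(z_h, z_l, n_high=500, n_low=500)
        assert cp.pp_high[0] > max(cp.pp_low[0], cp.pp_shared[0])
        assert cp.pp_high[0] > 0.8

    def test_shared_signal(self):
        z = np.concatenate([[8.0], np.zeros(19)])
        cp = finemap.config_posterior(z, z, n_high=500, n_low=500)
        assert cp.pp_shared[0] > max(cp.pp_high[0], cp.pp_low[0])

    def test_normalization_including_null(self):
        z_h = np.array([2.0, 1.0])
        z_l = np.array([0.5, 1.5])
        cp = finemap.config_posterior(z_h, z_l, n_high=300, n_low=300)
        total_h = cp.post_high.sum() + cp.null_high
        total_l = cp.post_low.sum() + cp.null_low
        assert total_h == pytest.approx(1.0, abs=1e-12)
        assert total_l == pytest.approx(1.0, abs=1e-12)

    def test_misaligned_raises(self):
        with pytest.raises(ValueError):
            finemap.config_posterior(np.zeros(3), np.zeros(4), n_high=100, n_low=100)


class TestCochranQ:
    def test_closed_form_worked_example(self):
        t = finemap.cochran_q(0.5, 0.1, 0.1, 0.1)
        assert t.Q == pytest.approx(8.0, abs=1e-12)
        assert t.p == pytest.approx(stats.chi2.sf(8.0, 1), rel=1e-12)
        assert t.p == pytest.approx(4.678e-3, rel=1e-3)

    def test_identical_effects(self):
        t = finemap.cochran_q(0.3, 0.05, 0.3, 0.08)
        assert t.Q == 0.0 and t.p == 1.0

    def test_group_label_swap_invariance(self):
        a = finemap.cochran_q(0.4, 0.1, -0.2, 0.3)
        b = finemap.cochran_q(-0.2, 0.3, 0.4, 0.1)
        assert a.Q == pytest.approx(b.Q, abs=1e-14)

    def test_equals_general_fixed_effect_form(self):
        # oracle: Q = sum w_i (b_i - b_FE)^2 with inverse-variance weights
        bh, sh, bl, sl = 0.7, 0.12, 0.2, 0.3
        w = np.array([1 / sh**2, 1 / sl**2])
        b = np.array([bh, bl])
        b_fe = (w * b).sum() / w.sum()
        q_general = float((w * (b - b_fe) ** 2).sum())
        assert finemap.cochran_q(bh, sh, bl, sl).Q == pytest.approx(q_general, abs=1e-12)

    def test_null_p_uniform(self, rng):
        se = 0.1
        b_true = rng.standard_normal(3000) * 0.2
        bh = b_true + rng.normal(0, se, 3000)
        bl = b_true + rng.normal(0, se, 3000)
        tests = finemap.cochran_q(bh, np.full(3000, se), bl, np.full(3000, se))
        ps = np.array([t.p for t in tests])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bad_se_raises(self):
        with pytest.raises(ValueError):
            finemap.cochran_q(0.1, 0.0, 0.2, 0.1)
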