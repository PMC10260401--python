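import numpy as np
import pytest

import admixqtl as aq


@pytest.fixture(scope="session")
def small_panel():
    """Three-population panel: high-diversity pop 0, bottlenecked pop 1."""
    return aq.simulate_ancestral_panel(
        n_pops=3,
        n_variants=600,
        n_genes=6,
        block_size=10,
        rho_per_pop=0.5,
        F=(0.05, 0.3, 0.15),
        seed=101,
        private_fraction=0.08,
    )


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    theta = aq.two_group_theta(300, 3, focal_pop=0, seed=102)
    return aq.simulate_admixed_genotypes(small_panel, 300, theta=theta, seed=103)


@pytest.fixture(scope="session")
def small_expression(small_panel, small_cohort):
    scenarios = ["shared", "tier1", "tier2", "tier3", "null", "shared"]
    return aq.simulate_expression(
        small_cohort, small_panel, {"scenarios": scenarios, "h2": 0.2}, seed=104
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
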