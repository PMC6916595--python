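import numpy as np
import pytest

import treeletomics as tm


def three_block_data(n, rng, sizes=(10, 8, 6), within_corr=0.7):
    """Variables grouped in independent equicorrelated blocks."""
    lam, eps = np.sqrt(within_corr), np.sqrt(1.0 - within_corr)
    cols = []
    for k in sizes:
        u = rng.standard_normal((n, 1))
        cols.append(lam * u + eps * rng.standard_normal((n, k)))
    return np.hstack(cols)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def panel():
    return tm.build_panel()


@pytest.fixture(scope="session")
def null_cohort(panel):
    """200 matched sets with no latent effect and a realistic outcome mix."""
    cohort = tm.simulate_matched_pairs(
        panel, tm.EffectSpec(), 200, outcome="overall", seed=101)
    return tm.assign_outcomes(cohort, seed=102)


@pytest.fixture(scope="session")
def effect_cohort(panel):
    """300 matched sets where the phospholipid block lowers case odds."""
    effects = tm.EffectSpec({("block1", "advanced"): 0.6})
    return tm.simulate_matched_pairs(
        panel, effects, 300, outcome="advanced", seed=103)
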