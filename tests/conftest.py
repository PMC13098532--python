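import numpy as np
import pytest

from gxekit.genetics_sim import EffectProfile, simulate_families


@pytest.fixture(scope="session")
def effects50():
    """Uniform direct effects over 50 SNPs with symmetric nurture."""
    return EffectProfile.uniform(50, nurture_mother=0.3, nurture_father=0.3)


@pytest.fixture(scope="session")
def small_families(effects50):
    """2,000 single-child trio families, random mating."""
    return simulate_families(2000, 50, effects50, seed=123)


@pytest.fixture(scope="session")
def sibling_families(effects50):
    """1,000 families with two children each."""
    return simulate_families(1000, 50, effects50, children_per_family=2, seed=321)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
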