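import numpy as np
import pytest

import famcombine as fc


@pytest.fixture(scope="session")
def small_study():
    """4 three-generation families (168 individuals), one ~30-variant gene."""
    cfg = fc.SimConfig(n_families=4, h2=0.3, seed=42)
    return fc.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_fit(small_study):
    model = fc.FamilialLMM.from_phenotype_data(small_study.trait, small_study.kinship)
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
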