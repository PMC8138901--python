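import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gexmorph as gx
from gexmorph.synthetic import CohortSpec, ExpressionSpec

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scenario():
    """One default synthetic study shared by read-only tests."""
    return gx.gen_scenario(0)


@pytest.fixture(scope="session")
def small_cohort():
    """Cross-sectional cohort (one visit each) for sandwich/HC0 identities."""
    spec = CohortSpec(n_per_group={"control": 30, "persistent": 30},
                      visits_per_subject=1, seed=1)
    return gx.gen_cohort(spec, gx.default_regions(5))


@pytest.fixture(scope="session")
def fitted(scenario):
    """Sandwich GLM fitted on the default scenario."""
    return gx.SandwichGLM().fit(scenario.dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_association():
    """A 200-gene association table with deterministic pseudo-random rho."""
    r = np.random.default_rng(7)
    genes = [f"G{i:04d}" for i in range(200)]
    return pd.DataFrame({"rho": r.uniform(-1, 1, 200)},
                        index=pd.Index(genes, name="gene"))
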