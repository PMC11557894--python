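import numpy as np
import pytest

import taskspace as ts


@pytest.fixture(scope="session")
def small_cohort():
    return ts.generate_cohort(n_subjects=60, sibling_fraction=0.5, seed=101)


@pytest.fixture(scope="session")
def small_basis():
    return ts.generate_gradients(n_vertices=1000, n_dims=3, seed=1)


@pytest.fixture(scope="session")
def null_effects():
    return ts.EffectSpec.null()


@pytest.fixture(scope="session")
def null_table(small_cohort, null_effects):
    return ts.generate_coordinates(small_cohort, null_effects, seed=202)


@pytest.fixture(scope="session")
def small_mapset(small_cohort, small_basis, null_effects):
    return ts.generate_maps(
        small_cohort, small_basis, null_effects, conditions=ts.CONDITIONS[:3], seed=303
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
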