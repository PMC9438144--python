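import numpy as np
import pytest
from hypothesis import settings

import mirnanet as mn
from mirnanet.pipeline import _design_matrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A moderate three-group simulated study shared across tests."""
    cfg = mn.SimulationConfig(
        n_mirna=200,
        n_gene=400,
        planted_de=mn.default_planted_effects(200, 20, rng_seed=1),
        seed=1,
    )
    cm, design, truth = mn.simulate_counts(cfg)
    return cfg, cm, design, truth


@pytest.fixture(scope="session")
def normalized(small_study):
    cfg, cm, design, truth = small_study
    return mn.normalize(cm, _design_matrix(design))


@pytest.fixture(scope="session")
def two_group_study():
    """8 vs 8 two-group design with strong planted effects."""
    ids = mn.simulate.mirna_ids(150)
    planted = {ids[i]: (1.5 if (i // 2) % 2 == 0 else -1.5) for i in range(0, 40, 2)}
    cfg = mn.SimulationConfig(
        n_mirna=150,
        n_gene=300,
        n_per_group={"healthy": 8, "interictal": 8},
        planted_de=planted,
        dispersion=0.1,
        seed=7,
    )
    cm, design, truth = mn.simulate_counts(cfg)
    return cfg, cm, design, truth
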