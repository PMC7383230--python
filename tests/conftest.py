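"""Shared fixtures: small seeded synthetic screens."""

import numpy as np
import pytest

from crispra_screen import SimulationConfig
from crispra_screen.simulate import generate_cells, generate_library


def small_config(**overrides) -> SimulationConfig:
    params = dict(
        n_target_genes=8,
        sgrnas_per_target=2,
        n_nontargeting=4,
        cells_per_sgrna=30,
        n_genes=300,
        n_signature_genes=40,
        n_mito_genes=5,
        n_true_hits=4,
        seed=0,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture
def config():
    return small_config()


@pytest.fixture(scope="session")
def small_screen():
    cfg = small_config()
    rng = np.random.default_rng(cfg.seed)
    library = generate_library(cfg, rng)
    matrix, truth = generate_cells(cfg, library, rng)
    return {"config": cfg, "library": library, "matrix": matrix, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
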