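import numpy as np
import pandas as pd
import pytest

from mucoseq.gem import default_diet, fermentation_universe
from mucoseq.synth import GeneratorConfig, generate_read_counts, generate_world


def small_config(**kw) -> GeneratorConfig:
    """Scaled-down study: same structure, lighter depths for fast tests."""
    defaults = dict(
        n_subjects=5, n_mgs=15, genes_per_mgs=110, n_centroids=30,
        depth_biopsy=80_000, depth_faeces=90_000, seed=11,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def world_and_reads():
    cfg = small_config()
    world = generate_world(cfg)
    return cfg, world, generate_read_counts(world, cfg)


@pytest.fixture(scope="session")
def universe():
    return fermentation_universe()


@pytest.fixture(scope="session")
def diet():
    return default_diet()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
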