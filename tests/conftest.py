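import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240110)


@pytest.fixture(scope="session")
def tiny_colony():
    """Small call-only colony shared by file-level pipeline tests."""
    from rookvoc import synthetic

    config = synthetic.balanced_colony(
        n_archetypes=3, n_individuals=2, units_per_individual=12, seed=5
    )
    return synthetic.generate_colony(config)


@pytest.fixture(scope="session")
def tiny_pipeline_config():
    from rookvoc import pipeline

    return pipeline.PipelineConfig(
        n_neighbors=8, min_samples=4, min_cluster_size=4, quality_k=5, seed=5
    )
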