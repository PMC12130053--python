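import numpy as np
import pandas as pd
import pytest

import befpart as bp


@pytest.fixture
def paper_design() -> bp.DesignConfig:
    """Five species, richness {1,2,4}, four treatments, five replicates."""
    return bp.DesignConfig(seed=11)


@pytest.fixture
def paper_pots(paper_design) -> list[bp.PotRecord]:
    return bp.enumerate_design(paper_design)


@pytest.fixture
def generated(paper_design):
    """A full noisy synthetic experiment on the canonical design."""
    cfg = bp.default_config(seed=11)
    individuals, truth = bp.generate_experiment(cfg)
    return cfg, individuals, truth


def random_partition_instance(rng: np.random.Generator):
    """A random mixture: N in 2..8, positive baselines, non-negative yields."""
    n = int(rng.integers(2, 9))
    species = [f"S{i}" for i in range(n)]
    m = dict(zip(species, rng.uniform(0.5, 50.0, n)))
    y = dict(zip(species, rng.uniform(0.0, 40.0, n)))
    return y, m
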