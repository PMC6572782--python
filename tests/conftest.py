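"""Shared fixtures: synthetic fields and fully processed pipeline results.

Session-scoped so the rendered stacks and the segmentation/detection work
are shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from smfishquant import RunConfig, pipeline, synthetic
from smfishquant.synthetic import SceneSpec


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def default_field():
    """One default 12x256x256 field with ~20 cells and Poisson spot counts."""
    return synthetic.generate_field(SceneSpec(seed=1))


@pytest.fixture(scope="session")
def processed_field(default_field, config):
    """The default field pushed through segmentation, thresholding, counting."""
    stack, truth = default_field
    results = pipeline.process_stacks([stack], config)
    result = results[0]
    mapping = synthetic.match_cells(truth, result.records)
    return stack, truth, result, mapping


@pytest.fixture(scope="session")
def empty_field():
    """A pure-background field: no cells, no spots."""
    return synthetic.generate_field(SceneSpec(seed=7, n_cells=0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
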