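"""Shared fixtures.

The expensive session fixtures (the full committor-learning pipeline, the
brute-force oracle grid and the direct-simulation reference TP ensemble) are
built once and shared between the unit suite and the acceptance suite.
"""

import numpy as np
import pytest

from dimerpath.landscape import (ToyLandscapeSpec, brute_force_committor,
                                 harvest_transition_paths)
from dimerpath.pipeline import learn_toy_committor, transition_region_grid


@pytest.fixture(scope="session")
def default_spec():
    return ToyLandscapeSpec()


@pytest.fixture(scope="session")
def toy_pipeline(default_spec):
    """Full committor-learning pipeline on the default landscape (seed 0)."""
    run, model, dynamics = learn_toy_committor(default_spec, seed=0)
    return run, model, dynamics


@pytest.fixture(scope="session")
def oracle_grid(default_spec):
    """Brute-force committor (500 shots/point) on the 15x15 transition grid."""
    points = transition_region_grid(default_spec, n=15)
    return brute_force_committor(default_spec, points, 500, seed=1)


@pytest.fixture(scope="session")
def reference_ensemble(default_spec):
    """Unbiased TP ensemble harvested from long direct simulation."""
    return harvest_transition_paths(default_spec, 400, seed=99,
                                    chunk_steps=8_000_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
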