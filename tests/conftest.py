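"""Shared fixtures: a reduced-scale corpus and trained ensemble.

The reduced profile (50 models per class, narrow networks) keeps the
session fast while exercising the full generate -> train -> predict
path; fixtures are session-scoped so training happens once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from bifurcell.dataset import generate_dataset
from bifurcell.nn import Ensemble, NetworkSpec, train

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

SCALED_SEED = 3


@pytest.fixture(scope="session")
def scaled_dataset():
    """50 models/class corpus: 4000 series, split 3800/100/100."""
    return generate_dataset(n_models_per_class=50, shuffle_seed=SCALED_SEED)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 models/class corpus: 160 series, for smoke tests."""
    return generate_dataset(n_models_per_class=2, shuffle_seed=7)


@pytest.fixture(scope="session")
def scaled_nets(scaled_dataset):
    """One trained reduced-width network per variant, with histories."""
    out = {}
    for variant in (1, 2):
        net, hist = train(scaled_dataset, NetworkSpec.scaled(variant),
                          seed=10 + variant, epochs_max=60, batch_size=256,
                          patience=10)
        out[variant] = (net, hist)
    return out


@pytest.fixture(scope="session")
def scaled_ensemble(scaled_nets):
    return Ensemble([scaled_nets[1][0], scaled_nets[2][0]])
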