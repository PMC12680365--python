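"""Shared fixtures.

The expensive end-to-end artefacts (a trained desk-scale model and its
evaluation) are session-scoped so the accuracy, uncertainty and
reproducibility properties can all probe one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from fundusgcn.phantoms import PhantomSpec, generate_samples
from fundusgcn.pipeline import desk_spec, run_pipeline
from fundusgcn.training import TrainConfig


@pytest.fixture(scope="session")
def small_samples():
    """300 phantoms at 48 px with mild imbalance: quick pipeline food."""
    spec = PhantomSpec(
        image_size=48,
        class_counts={0: 120, 1: 75, 2: 45, 3: 35, 4: 25},
        seed=7,
    )
    return generate_samples(spec)


@pytest.fixture(scope="session")
def desk_run():
    """The reference desk-scale run: 1,000 phantoms, 10 epochs, seed 42."""
    return run_pipeline(desk_spec(seed=42), TrainConfig(epochs=10, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
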