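"""Shared fixtures: small synthetic datasets, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from parnet import SynthSpec, generate_activity_dataset


@pytest.fixture(scope="session")
def temporal_pair():
    """Two classes that differ only in arm-leg phase ordering."""
    spec = SynthSpec(n_classes=2, n_sequences_per_class=100,
                     frames_per_sequence=30,
                     signal_mix=("temporal", "temporal"), seed=11)
    table, truth = generate_activity_dataset(spec)
    return table, truth


@pytest.fixture(scope="session")
def spatial_pair():
    """Two classes that differ only in static pose geometry."""
    spec = SynthSpec(n_classes=2, n_sequences_per_class=100,
                     frames_per_sequence=30,
                     signal_mix=("spatial", "spatial"), seed=12)
    table, truth = generate_activity_dataset(spec)
    return table, truth


@pytest.fixture(scope="session")
def mixed_dataset():
    """Five classes mixing spatial, temporal and combined signatures."""
    spec = SynthSpec(n_classes=5, n_sequences_per_class=100,
                     frames_per_sequence=30, seed=42)
    table, truth = generate_activity_dataset(spec)
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
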