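"""Shared fixtures: phantom panels and trained models reused across tests.

Everything is generated programmatically at fixed seeds; the heavier
trained-model fixtures are session-scoped so the cost is paid once.
"""

import numpy as np
import pytest

from fluorosep import features, phantoms
from fluorosep.phantoms import NoiseSpec, PatternSpec

PANEL_SHAPE = (128, 128, 8)

# a faint nonspecific-staining haze keeps sparse fields normalizable, as
# real singly stained tissue fields are
PANEL4_LABELS = [
    ("fibA", PatternSpec("filament", density=1.5, size_um=3.0, haze=0.05)),
    ("fibB", PatternSpec("filament", density=3.0, size_um=2.0, haze=0.05)),
    ("nucA", PatternSpec("blob", density=4.0, size_um=2.5, haze=0.05)),
    ("nucB", PatternSpec("blob", density=8.0, size_um=1.5, haze=0.05)),
]

FIBROUS = {"fibA", "fibB"}
GLOBULAR = {"nucA", "nucB"}


@pytest.fixture(scope="session")
def panel4():
    """Two-filament + two-blob panel, 2 stacks per protein (1 train, 1 test)."""
    return phantoms.generate_panel(
        PANEL4_LABELS, n_stacks=2, shape=PANEL_SHAPE, seed=42
    )


@pytest.fixture(scope="session")
def embedder4(panel4):
    """One contrastive embedding fitted on the 4-protein panel."""
    cfg = features.FeatureExtractorConfig(seed=1, epochs=60, batch_size=32)
    return features.PatternEmbedder(panel4, cfg).fit()


@pytest.fixture(scope="session")
def registered_pair():
    """A distinct-family (filament, blob) registered channel pair."""
    specA = PatternSpec("filament", density=1.5, size_um=3.0, haze=0.05)
    specB = PatternSpec("blob", density=4.0, size_um=2.5, haze=0.05)
    train = phantoms.generate_registered_pair(specA, specB, shape=(96, 96, 8), seed=1)
    test = phantoms.generate_registered_pair(specA, specB, shape=(96, 96, 8), seed=2)
    return train, test


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
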