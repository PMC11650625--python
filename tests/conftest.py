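from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from niend import PhantomSpec, SWCMorphology, SWCNode, make_phantom

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A fast phantom small enough for per-test use, as sparse (<1% cable
    volume) as the soma-centered blocks the pipeline is meant for."""
    return PhantomSpec(shape=(24, 96, 96), n_neurites=2, neurite_steps=80,
                       soma_radius=4.0, seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    """The study-condition block: (64, 256, 256), sparse, 16-bit."""
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return make_phantom(default_spec)


def straight_line_morph(length: float = 2000.0, spacing: float = 2.0,
                        radius: float = 1.0) -> SWCMorphology:
    """A straight polyline along +x — a gold standard that never approaches
    itself, so displaced-fraction fixtures have exact expected deviations."""
    n = int(length / spacing)
    nodes = [SWCNode(1, 1, 0.0, 0.0, 0.0, radius, -1)]
    for i in range(1, n + 1):
        nodes.append(SWCNode(i + 1, 3, i * spacing, 0.0, 0.0, radius, i))
    return SWCMorphology(nodes, provenance="straight_line")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
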