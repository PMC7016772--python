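"""Shared fixtures: small seeded genomes, depth tracks and read sets.

Everything is generated programmatically at test time; no data files ship
with the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from gclens import (
    BiasModel,
    ContigSpec,
    GenomeSpec,
    gc_gradient_genome,
    simulate_depth,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_assembly():
    """Three contigs sweeping low/mid/high GC, ~30 kb each."""
    spec = GenomeSpec(
        contigs=(
            ContigSpec("low_gc", ((32.0, 15_000), (38.0, 15_000))),
            ContigSpec("mid_gc", ((46.0, 15_000), (52.0, 15_000))),
            ContigSpec("high_gc", ((60.0, 15_000), (66.0, 15_000))),
        ),
        seed=7,
    )
    return simulate_genome(spec)


@pytest.fixture(scope="session")
def small_tracks(small_assembly):
    """Unbiased 20x depth over the small assembly."""
    return simulate_depth(small_assembly, BiasModel(kind="none"), 20.0, seed=8)


@pytest.fixture(scope="session")
def gradient_assembly():
    """One 400 kb contig sweeping GC 30-70 (populates many 1% bins)."""
    spec = gc_gradient_genome(length=400_000, n_segments=20, seed=9)
    return simulate_genome(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
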