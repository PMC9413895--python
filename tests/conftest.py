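"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from retroquant.align import ReferenceGenome
from retroquant.simulate import SimConfig, build_genome, simulate_cells


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ref() -> ReferenceGenome:
    """A 20 kb two-contig random reference for aligner unit tests."""
    r = np.random.default_rng(777)
    return ReferenceGenome(
        {"chr1": _random_genome(r, 15_000), "chr2": _random_genome(r, 5_000)}
    )


@pytest.fixture(scope="session")
def small_sim():
    """A desk-scale simulated study reused across unit tests."""
    cfg = SimConfig(
        seed=42,
        genome_length=150_000,
        n_repeat_copies=16,
        n_expressed=5,
        n_passive=5,
        n_cells=30,
        reads_per_cell=400,
        bulk_fragments=8_000,
    )
    genome = build_genome(cfg)
    reads = simulate_cells(cfg, genome)
    return cfg, genome, reads
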