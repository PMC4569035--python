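"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pytest

import msatld as m
from msatld.simulate import stable_small


@pytest.fixture(scope="session")
def stable_sim():
    """Stable population of 220, sampled in its final year; fixed seed."""
    return m.simulate_population(stable_small(), seed=5)


@pytest.fixture(scope="session")
def small_sim():
    """A quick multi-year panel for I/O, filtering and relatedness tests."""
    sc = m.Scenario(
        name="mini", n_chromosomes=4, loci_per_chromosome=4,
        census=[(0, 60), (9, 60)], sampled_years=(6, 9),
    )
    return m.simulate_population(sc, seed=17)


@pytest.fixture(scope="session")
def stable_pairs(stable_sim):
    """Pairwise LD over the full stable panel (both metrics)."""
    return m.pairwise_ld(stable_sim.gm, stable_sim.lmap)
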