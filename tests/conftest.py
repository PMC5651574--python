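"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from goatpop.qc import apply_qc
from goatpop.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """4 breeds × 24 animals, 3000 loci, one drifted breed, planted outliers."""
    return simulate(SimConfig(n_loci=3000, seed=7))


@pytest.fixture(scope="session")
def small_qc(small_sim):
    gm, report = apply_qc(small_sim.genotypes, small_sim.snps)
    return gm, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
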