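import numpy as np
import pytest

import gpqtl
from gpqtl import interval_mapping as im


@pytest.fixture(scope="session")
def small_cross():
    """3 chromosomes x 40 markers, 120 offspring; deterministic."""
    cfg = gpqtl.CrossSimConfig(
        n_offspring=120, n_chromosomes=3, markers_per_chromosome=40,
        chrom_length_cM=60.0, seed=42,
    )
    gm, geno = gpqtl.simulate_cross(cfg)
    return cfg, gm, geno


@pytest.fixture(scope="session")
def small_design(small_cross):
    _, gm, geno = small_cross
    return gm, geno, gpqtl.encode_design(geno)


@pytest.fixture(scope="session")
def small_probgrid(small_cross):
    _, gm, geno = small_cross
    return im.calc_genoprob(geno, gm, step_cM=None)


@pytest.fixture(scope="session")
def big_cross():
    """Full-size synthetic cross: 188 offspring, 3,961 markers."""
    cfg = gpqtl.CrossSimConfig(seed=7)
    gm, geno = gpqtl.simulate_cross(cfg)
    return cfg, gm, geno


@pytest.fixture(scope="session")
def big_design(big_cross):
    _, gm, geno = big_cross
    return gm, geno, gpqtl.encode_design(geno)


def planted_trait(design, gm, s, h2, seed, distribution="same", **kw):
    cfgsim = gpqtl.SimulationConfig(
        s=s, h2=h2, distribution=distribution, base_seed=seed, **kw
    )
    return gpqtl.trait_sim.simulate_replicate(design, gm, cfgsim)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
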