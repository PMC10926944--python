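import numpy as np
import pytest

from methpel import synthetic
from methpel.io import cpg_density


@pytest.fixture(scope="session")
def small_map():
    """~100 kb single-chromosome map with all feature classes present."""
    return synthetic.generate_cpg_map(n_chrom=1, chrom_length=100_000, island_fraction=0.15, seed=7)


@pytest.fixture(scope="session")
def small_pair(small_map):
    """Low-depth tumor/normal pair on the small map (shared across tests)."""
    return synthetic.make_tumor_normal_pair(small_map, seed=7, depth=6)


@pytest.fixture(scope="session")
def recovery_region():
    """20-CpG region with a dense upstream flank so rho varies across it.

    The flank (gap 2 bp) sits within the density window of the region's
    first sites, giving rho a spread of ~0.25-0.53 that identifies the
    density coefficient b.  Returns (rho, d) of the region chain.
    """
    flank = np.arange(1, 1000, 2)
    region = flank[-1] + 15 + np.arange(20) * 15
    pos = np.concatenate([flank, region])
    rho = cpg_density(pos)[-20:]
    d = np.diff(region).astype(float)
    return rho, d
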