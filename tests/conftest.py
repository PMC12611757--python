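import numpy as np
import pandas as pd
import pytest

from ecdnakit import synthetic_data as sd


@pytest.fixture(scope="session")
def genome_bundle():
    """One shared toy-genome bundle (genome, repeats, contacts, reads)."""
    return sd.simulate_genome_and_contacts(sd.GenomeSimConfig(seed=11))


@pytest.fixture(scope="session")
def small_spots():
    """300 clustered nuclei at default (hub) parameters."""
    return sd.simulate_nuclei(sd.NucleusSimConfig(n_cells=300, seed=11))


@pytest.fixture(scope="session")
def null_screen():
    return sd.simulate_guide_screen(sd.ScreenSimConfig(seed=11))


def toy_spot_table(rows):
    """rows: (cell_id, locus, x, y, z)."""
    return pd.DataFrame(rows, columns=["cell_id", "locus", "x_um", "y_um", "z_um"])


def csr_reference_sampler(rng, n, radius):
    """Independent rejection sampler for uniform points in a ball, written
    separately from the package so it can act as a CSR oracle."""
    pts = []
    while len(pts) < n:
        p = rng.uniform(-radius, radius, size=3)
        if (p**2).sum() <= radius**2:
            pts.append(p)
    return np.array(pts)
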