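import numpy as np
import pytest

from helixforge.fixtures import (make_helical_filament, make_noisy_model_map,
                                 make_toy_monomer)
from helixforge.model import AtomicModel


@pytest.fixture(scope="session")
def monomer():
    """20-residue toy monomer with Lys/Glu/Leu side chains at chi1=180."""
    return make_toy_monomer(20, with_sidechains=True, chi1=180.0)


@pytest.fixture(scope="session")
def monomer_map(monomer):
    """Noiseless Gaussian-atom map of the session monomer."""
    return make_noisy_model_map(monomer, voxel_size=0.7, b_offset=20.0)


@pytest.fixture(scope="session")
def filament():
    """5-subunit filament at the canonical actin-like symmetry."""
    return make_helical_filament((27.5, -167.2), 5, 20)


@pytest.fixture(scope="session")
def many_residue_model():
    """200 chi1-eligible residues packed into a compact box (null tests)."""
    chains = []
    for i in range(10):
        m = make_toy_monomer(20, with_sidechains=True, seed=i,
                             chain_id=chr(ord("A") + i))
        chains.append(m.translated(
            np.array([18.0 * (i % 5), 18.0 * (i // 5), 0.0])))
    return AtomicModel.concatenate(chains)
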