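import warnings

import numpy as np
import pytest

from survbind.atom_types import default_atom_type_map

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def atom_map():
    return default_atom_type_map()


@pytest.fixture(scope="session")
def small_array():
    """Moderate synthetic array shared by labeling/split/cluster tests."""
    from survbind.synthetic import gen_peptide_array

    proteins, peptides, measurements, gt = gen_peptide_array(
        n_proteins=6, length_range=(80, 200), seed=42
    )
    return proteins, peptides, measurements, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
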