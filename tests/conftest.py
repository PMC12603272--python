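import numpy as np
import pytest

from grooveqsar.fields import assemble_descriptor_matrix
from grooveqsar.qsar import run_protocols
from grooveqsar.synthetic import default_grid, make_synthetic_complexes

THREE_ATOM_PDB = """\
ATOM      1  P    DA A   1       1.000   2.000   3.000  0.00  0.00           P
ATOM      2  C4'  DA A   1       2.500   2.500   3.500  0.00  0.00           C
HETATM    3  C1  LIG X   1       0.500   0.700   0.900 -0.25  0.00           C
END
"""


@pytest.fixture(scope="session")
def three_atom_pdb() -> str:
    return THREE_ATOM_PDB


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def noiseless_dataset(grid):
    """28 noiseless congeneric complexes: 27 for training, 1 held out."""
    records, truth = make_synthetic_complexes(n=28, noise_sd=0.0, seed=11)
    return records, truth


@pytest.fixture(scope="session")
def noiseless_protocols(noiseless_dataset, grid):
    records, truth = noiseless_dataset
    train = records[:27]
    dm = assemble_descriptor_matrix(train, grid)
    y = np.array([r.pkd for r in train])
    reports = run_protocols(
        dm, y, [r.ligand_id for r in train], split_seed=3, max_components=18
    )
    return dm, y, reports
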