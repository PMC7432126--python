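import numpy as np
import pytest
from hypothesis import settings

from paedeg import tables
from paedeg.composite import ScoreMatrix, comprehensive_table
from paedeg.fields import Molecule
from paedeg.synthetic import SyntheticSpec, gen_molecule_set

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1_matrix() -> ScoreMatrix:
    raw = tables.load_table1_scores().set_index("compound")
    return ScoreMatrix.from_frame(raw[["2PIA", "2ZYI", "3CN7"]])


@pytest.fixture(scope="session")
def table1_result(table1_matrix):
    return comprehensive_table(table1_matrix, floor_a=0.9)


def make_molecule(mol_id, coords, **kwargs):
    """Molecule with neutral defaults for unspecified per-atom properties."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    defaults = dict(
        elements=["C"] * n,
        charge=np.zeros(n),
        vdw=np.ones(n),
        hydrophobicity=np.zeros(n),
        donor=np.zeros(n),
        acceptor=np.zeros(n),
    )
    defaults.update(kwargs)
    return Molecule(id=mol_id, coords=coords, **defaults)


@pytest.fixture(scope="session")
def noiseless_qsar_data():
    """30 aligned molecules with an exactly linear planted response."""
    return gen_molecule_set(SyntheticSpec(seed=7, n_compounds=30,
                                          noise_sd=0.0))
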