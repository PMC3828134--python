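import numpy as np
import pytest

from bsfp.core_model import Atom, Residue, Structure
from bsfp.fixtures import default_motif, make_toy_protein
from bsfp.sitegraph import CompareParams


@pytest.fixture
def params():
    return CompareParams()


@pytest.fixture
def toy_protein():
    return make_toy_protein(25, seed=7, struct_id="toy")


@pytest.fixture
def motif_protein():
    return make_toy_protein(30, default_motif(), seed=11, struct_id="query")


def make_residue(chain, number, name, atom_specs, hetero=False):
    """atom_specs: list of (atom_name, element, (x, y, z))."""
    atoms = [Atom(n, e, np.array(c, dtype=float)) for n, e, c in atom_specs]
    return Residue(chain, number, name, atoms, is_hetero=hetero)


def simple_structure(residues, struct_id="s"):
    return Structure(struct_id, residues)
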