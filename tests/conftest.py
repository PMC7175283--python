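import numpy as np
import pytest

from flexsig.structure import Atom, ProteinStructure, ResidueRef
from flexsig.synthetic import FeatureGenSpec, make_feature_dataset, make_helix_peptide


@pytest.fixture(scope="session")
def helix12():
    return make_helix_peptide(12, with_hbonds=True)


@pytest.fixture(scope="session")
def strand12():
    return make_helix_peptide(12, with_hbonds=False)


@pytest.fixture(scope="session")
def planted_matrix():
    return make_feature_dataset(FeatureGenSpec(seed=20260927))


def build_structure(residue_specs, source_id="fixture"):
    """Residue specs: (resname, [(atom_name, element, (x, y, z)), ...])."""
    residues = []
    serial = 0
    for i, (resname, atoms) in enumerate(residue_specs):
        atom_objs = []
        for name, element, coords in atoms:
            serial += 1
            atom_objs.append(Atom(serial=serial, name=name, element=element,
                                  coords=tuple(float(c) for c in coords)))
        residues.append(ResidueRef(chain="A", resnum=i + 1, resname=resname,
                                   atoms=atom_objs))
    return ProteinStructure(residues=residues, source_id=source_id)
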