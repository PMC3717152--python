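import numpy as np
import pytest

from modelcheck.model_qc import HBondCriteria
from modelcheck.structure_io import Atom, Residue, Structure, load_default_bw_map
from modelcheck.synthetic import BundleSpec, make_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default idealized 7TM bundle with M2-numbered landmark residues."""
    return make_bundle(BundleSpec(seed=0))


@pytest.fixture(scope="session")
def plain_bundle():
    """Larger generic bundle (250 residues) without landmark residues."""
    return make_bundle(BundleSpec(n_helices=5, residues_per_helix=50, with_special_residues=False))


@pytest.fixture(scope="session")
def bw_map():
    return load_default_bw_map()


@pytest.fixture
def criteria():
    return HBondCriteria()


def make_structure(residue_specs, structure_id="mini"):
    """Build a Structure from [(name, seq, {atom: xyz}), ...]."""
    st = Structure(id=structure_id)
    st.chains["A"] = [
        Residue(
            name=name,
            seq_number=seq,
            chain="A",
            atoms=[Atom(an, an[0] if an[0] in "CNOS" else "C", np.asarray(xyz, float))
                   for an, xyz in atoms.items()],
        )
        for name, seq, atoms in residue_specs
    ]
    return st.validate()


@pytest.fixture
def mini_builder():
    return make_structure
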