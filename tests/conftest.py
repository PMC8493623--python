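import pytest

from pixkit.fixtures import FIXTURE_NAMES, make_toy_crystal
from pixkit.molecule_builder import complete_molecules, normalize_h


@pytest.fixture(scope="session")
def toys():
    """All toy crystals, built once per session."""
    return {name: make_toy_crystal(name) for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def toy_molecules(toys):
    """Completed (and H-normalized where applicable) molecules per fixture."""
    out = {}
    for name, toy in toys.items():
        mols = complete_molecules(toy.structure)
        if any(a.element == "H" for m in mols for a in m.atoms):
            mols = [normalize_h(m) for m in mols]
        out[name] = mols
    return out


@pytest.fixture(scope="session")
def toy_molecules_raw(toys):
    """Completed molecules without H normalization (comparable to the
    raw-site brute-force oracle)."""
    return {name: complete_molecules(toy.structure)
            for name, toy in toys.items()}


@pytest.fixture(scope="session")
def tripalmitin():
    from pixkit.fixtures import build_tripalmitin
    return build_tripalmitin()


MINIMAL_P1_CIF = """\
data_minimal
_cell_length_a 5.0
_cell_length_b 5.0
_cell_length_c 5.0
_cell_angle_alpha 90.0
_cell_angle_beta 90.0
_cell_angle_gamma 90.0
loop_
_space_group_symop_operation_xyz
'x, y, z'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.0 0.0 0.0
"""


@pytest.fixture
def minimal_p1_cif():
    return MINIMAL_P1_CIF
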