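import numpy as np
import pytest

from swdock.energy import EnergyParameters
from swdock.structure import AtomRecord, StructureUnit, prepare_unit

BACKBONE = ("N", "CA", "C", "O", "OXT", "H")


def build_unit(specs, unit_id="u"):
    """Hand-built StructureUnit from (name, element, resname, resnum, xyz)."""
    atoms = []
    for i, (name, el, res, resi, xyz) in enumerate(specs):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=name,
                element=el,
                residue_name=res,
                residue_index=resi,
                chain_id="A",
                coords=np.array(xyz, dtype=float),
                is_hydrogen=(el == "H"),
                is_side_chain=name not in BACKBONE,
            )
        )
    return StructureUnit(atoms, unit_id)


@pytest.fixture
def params():
    return EnergyParameters()


@pytest.fixture
def donor_unit(params):
    """Serine-like hydroxyl: one donor/acceptor oxygen with its hydrogen."""
    u = build_unit([("OG", "O", "SER", 1, (0, 0, 0)), ("HG", "H", "SER", 1, (0.95, 0, 0))], "donor")
    return prepare_unit(u, ph=7.2, params=params)


@pytest.fixture
def acceptor_unit(params):
    """Backbone-like carbonyl: one acceptor oxygen plus a carbon."""
    u = build_unit([("O", "O", "GLY", 1, (0, 0, 0)), ("C", "C", "GLY", 1, (1.23, 0, 0))], "acceptor")
    return prepare_unit(u, ph=7.2, params=params)
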