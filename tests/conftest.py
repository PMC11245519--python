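from __future__ import annotations

import numpy as np
import pytest

from dcachepu.io_formats import Atom, StructureModel
from dcachepu.motif_model import MotifDefinition
from dcachepu.reference_synthetic import reference_anchor


@pytest.fixture(scope="session")
def anchor():
    return reference_anchor()


@pytest.fixture(scope="session")
def default_motif():
    return MotifDefinition.default()


def make_atom(
    serial,
    x,
    y,
    z,
    atom_name="CA",
    element="C",
    residue_name="ALA",
    chain_id="A",
    residue_seq=1,
    het=False,
):
    return Atom(serial, atom_name, element, residue_name, chain_id, residue_seq, x, y, z, het)


@pytest.fixture
def toy_structure():
    """Builder for small in-memory structures from atom tuples."""

    def build(atoms):
        return StructureModel(tuple(atoms))

    return build


def pdb_line(record, serial, name, resname, chain, resseq, x, y, z, element):
    """One fixed-column ATOM/HETATM line."""
    return (
        f"{record:<6}{serial:>5} {name:<4}{'':1}{resname:<3} {chain}{resseq:>4}    "
        f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{1.0:>6.2f}{0.0:>6.2f}          {element:>2}\n"
    )


@pytest.fixture
def pdb_writer(tmp_path):
    """Write a list of (record, serial, name, resname, chain, resseq, x, y, z, element)."""

    def write(rows, name="toy.pdb"):
        path = tmp_path / name
        path.write_text("".join(pdb_line(*row) for row in rows) + "END\n")
        return path

    return write


@pytest.fixture
def rng():
    return np.random.default_rng(20240712)
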