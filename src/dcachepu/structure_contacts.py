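"""Ligand-contact extraction from a receptor–ligand structure.

The purine-binding motif is anchored in the residues that touch the bound
ligand in the reference complex (uric acid in the McpH ligand-binding
domain).  A residue counts as contacting when any of its heavy atoms lies
within a distance cutoff (default 3.5 Å) of any heavy ligand atom.
Hydrogens are ignored throughout: at ~2 Å resolution they are not placed
reliably, and a heavy-atom rule is reproducible across models.

Two light-weight interaction labels are attached to each contact:

* ``hydrogen-bond-capable`` — the closest atom pair is N/O vs N/O at or
  below the cutoff (donor/acceptor geometry is not checked);
* ``aromatic-proximal`` — the residue is F/Y/W/H and a side-chain ring
  atom sits within cutoff + 1.0 Å of a ligand ring atom.  π-stacking is
  not geometrically verified (no plane-angle test); the label only marks
  candidates for the sandwich interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy.spatial.distance import cdist

from .io_formats import Atom, StructureModel

HYDROGEN_ELEMENTS = {"H", "D"}
HBOND_ELEMENTS = {"N", "O"}
AROMATIC_RESIDUES = {"PHE", "TYR", "TRP", "HIS"}

#: side-chain ring atom names of the aromatic residues
RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}

InteractionLabel = Literal["hydrogen-bond-capable", "aromatic-proximal", "other"]


@dataclass(frozen=True)
class LigandSelector:
    """Selects the het group to analyse, e.g. URC for uric acid."""

    het_residue_name: str
    chain_id: str | None = None

    def matches(self, atom: Atom) -> bool:
        return (
            atom.het_flag
            and atom.residue_name == self.het_residue_name
            and (self.chain_id is None or atom.chain_id == self.chain_id)
        )


@dataclass
class ContactRecord:
    """One ligand-contacting residue (minimum over heavy-atom pairs)."""

    residue_name: str
    residue_seq: int
    chain_id: str
    min_distance: float
    interaction_label: InteractionLabel = "other"


class LigandNotFoundError(ValueError):
    pass


def _heavy(atoms: Iterable[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element not in HYDROGEN_ELEMENTS]


def _coords(atoms: list[Atom]) -> np.ndarray:
    return np.array([(a.x, a.y, a.z) for a in atoms], dtype=float).reshape(len(atoms), 3)


def find_ligand_contacts(
    structure: StructureModel, ligand: LigandSelector, cutoff: float = 3.5
) -> list[ContactRecord]:
    """Residues with any heavy atom within ``cutoff`` Å of a heavy ligand atom.

    Records are sorted by residue_seq (then chain); ``min_distance`` is the
    minimal heavy-atom pair distance for that residue.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_atoms = _heavy(a for a in structure.atoms if ligand.matches(a))
    if not lig_atoms:
        raise LigandNotFoundError(
            f"no het atoms for residue {ligand.het_residue_name!r}"
            + (f" chain {ligand.chain_id!r}" if ligand.chain_id else "")
        )
    prot_atoms = _heavy(structure.protein_atoms())
    if not prot_atoms:
        raise ValueError("structure has no protein heavy atoms")

    dists = cdist(_coords(prot_atoms), _coords(lig_atoms))
    per_atom_min = dists.min(axis=1)
    best: dict[tuple[str, int, str], float] = {}
    for atom, d in zip(prot_atoms, per_atom_min):
        key = (atom.chain_id, atom.residue_seq, atom.residue_name)
        if d < best.get(key, np.inf):
            best[key] = d
    return [
        ContactRecord(resname, seq, chain, float(d))
        for (chain, seq, resname), d in sorted(
            best.items(), key=lambda kv: (kv[0][1], kv[0][0])
        )
        if d <= cutoff
    ]


def label_contacts(
    contacts: list[ContactRecord],
    structure: StructureModel,
    ligand: LigandSelector,
    cutoff: float = 3.5,
    aromatic_extra: float = 1.0,
) -> list[ContactRecord]:
    """Fill interaction labels on contact records (returns new records)."""
    lig_atoms = _heavy(a for a in structure.atoms if ligand.matches(a))
    if not lig_atoms:
        raise LigandNotFoundError(f"no het atoms for {ligand.het_residue_name!r}")
    # ligand ring atoms: C/N heavy atoms (the purine/pyrimidine ring skeleton)
    lig_ring = [a for a in lig_atoms if a.element in {"C", "N"}]
    lig_xyz = _coords(lig_atoms)
    lig_ring_xyz = _coords(lig_ring) if lig_ring else np.empty((0, 3))

    labelled: list[ContactRecord] = []
    for c in contacts:
        res_atoms = _heavy(
            a
            for a in structure.protein_atoms()
            if a.chain_id == c.chain_id and a.residue_seq == c.residue_seq
        )
        d = cdist(_coords(res_atoms), lig_xyz)
        i, j = np.unravel_index(int(np.argmin(d)), d.shape)
        label: InteractionLabel = "other"
        pair = {res_atoms[i].element, lig_atoms[j].element}
        if pair <= HBOND_ELEMENTS and d[i, j] <= cutoff:
            label = "hydrogen-bond-capable"
        elif c.residue_name in AROMATIC_RESIDUES and len(lig_ring):
            ring_names = RING_ATOMS[c.residue_name]
            ring_atoms = [a for a in res_atoms if a.atom_name in ring_names]
            if ring_atoms:
                ring_d = cdist(_coords(ring_atoms), lig_ring_xyz)
                if ring_d.min() <= cutoff + aromatic_extra:
                    label = "aromatic-proximal"
        labelled.append(
            ContactRecord(c.residue_name, c.residue_seq, c.chain_id, c.min_distance, label)
        )
    return labelled


def propose_binding_positions(contacts: Iterable[ContactRecord]) -> list[int]:
    """Ascending, de-duplicated residue indices of the contact set.

    This is the candidate set handed to conservation analysis; an empty
    contact list yields an empty proposal.
    """
    return sorted({c.residue_seq for c in contacts})
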