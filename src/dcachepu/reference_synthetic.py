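"""Synthetic stand-in for the reference purine-sensor domain and panel.

The real reference receptor (the McpH ligand-binding domain, PDB 8BMV) and
the experimentally tested receptor panel are not redistributed here; this
module provides *synthetic* stand-ins that reproduce every property the
pipeline relies on, in the reference's full-length residue numbering:

* motif residues Y121, R129, W140, F167, D169 and the companion aromatic
  F141;
* the further ligand-contacting but non-conserved positions (T123, N154,
  I155, D156, G159) completing the ten-residue contact set;
* a six-member receptor panel carrying the motif variants of the tested
  receptors (YRWFN, YKWYN, YRWFD, FRFYN, YKWFN, YHWFN), some with small
  flank indels so alignment anchoring is exercised.

The background residues are a fixed draw from a globular-domain
composition; everything in this module is a frozen constant, not data from
the study.
"""

from __future__ import annotations

import numpy as np

from .align_map import ReferenceAnchor
from .io_formats import AlignedBlock, SequenceRecord

#: full-length index of the first residue of the domain (offset 94)
NUMBERING_OFFSET = 94

#: synthetic reference domain, full-length positions 95..280
REFERENCE_RESIDUES = (
    "PGAASVNRLVSATARETLGKADQPNIYYTPQIDRRGLVVIMGNHIWFPCTSFTAHEKSFN"
    "IDCNGQEVIDPVFVDKPYVKSLLSKRRVDRVWATYWDYVSLFSVGLKVARNARASLVATA"
    "HKWMGFVFDGNLSMGKSPWILNTDKVASKTAIAPGQVDTAIKLYSGGTVLHYGETSQWVRTFDQRE"
)

#: the ten ligand-contacting positions of the reference complex
CONTACT_POSITIONS = (121, 123, 129, 140, 154, 155, 156, 159, 167, 169)

#: motif anchor positions and the structural (non-contacting) aromatic
ANCHOR_POSITIONS = (121, 129, 140, 167, 169)
COMPANION_POSITION = 141

#: motif variants of the six-member synthetic receptor panel
PANEL_VARIANTS = ("YRWFN", "YKWYN", "YRWFD", "FRFYN", "YKWFN", "YHWFN")


def reference_record() -> SequenceRecord:
    """The synthetic reference domain as a SequenceRecord."""
    return SequenceRecord("MCPH_LBD_SYNTHETIC", REFERENCE_RESIDUES,
                          "synthetic stand-in reference dCache_1 domain")


def reference_anchor() -> ReferenceAnchor:
    """Reference anchor with the default motif positions (Y121...D169, F141)."""
    return ReferenceAnchor(
        reference_record=reference_record(),
        anchor_positions=ANCHOR_POSITIONS,
        companion_position=COMPANION_POSITION,
        numbering_offset=NUMBERING_OFFSET,
    )


def _substitute(residues: str, full_position: int, letter: str) -> str:
    idx = full_position - NUMBERING_OFFSET - 1
    return residues[:idx] + letter + residues[idx + 1 :]


def synthetic_receptor_panel() -> list[SequenceRecord]:
    """Six synthetic receptors carrying the tested panel's motif variants.

    Variants are planted by substituting the motif positions of the
    reference backbone; three members additionally carry small flank or
    inter-motif indels so that alignment-anchored scanning is non-trivial.
    """
    records = []
    for i, variant in enumerate(PANEL_VARIANTS, start=1):
        residues = REFERENCE_RESIDUES
        for pos, letter in zip(ANCHOR_POSITIONS, variant):
            residues = _substitute(residues, pos, letter)
        if i == 2:  # N-terminal flank deletion (2 residues)
            residues = residues[2:]
        elif i == 4:  # insertion between companion and P4 (full pos ~150)
            k = 150 - NUMBERING_OFFSET
            residues = residues[:k] + "GS" + residues[k:]
        elif i == 6:  # C-terminal flank deletion
            residues = residues[:-3]
        records.append(
            SequenceRecord(f"R{i}_SYNTHETIC", residues, f"synthetic receptor, variant {variant}")
        )
    return records


def synthetic_cohort_alignment(
    variant_counts: dict[str, int] | None = None,
    background_mutation_rate: float = 0.3,
    seed: int = 0,
) -> AlignedBlock:
    """A gapless reference-anchored cohort alignment with planted variants.

    Every row is the reference backbone with the motif positions replaced
    by a variant's letters and a fraction of the remaining positions
    (including the non-motif contact positions, but never the companion
    aromatic) resampled from a uniform background — so motif columns stay
    conserved while the other contact columns are not, mirroring the
    conservation pattern the motif is derived from.
    """
    if variant_counts is None:
        variant_counts = {"YKWFN": 28, "YRWFN": 16, "YKWYN": 4,
                          "YRWFD": 4, "FRFYN": 4, "YHWFN": 4}
    rng = np.random.default_rng(seed)
    protected = set(ANCHOR_POSITIONS) | {COMPANION_POSITION}
    rows = [(reference_record().identifier, REFERENCE_RESIDUES)]
    i = 0
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    for variant, count in sorted(variant_counts.items()):
        for _ in range(count):
            i += 1
            residues = REFERENCE_RESIDUES
            for pos, letter in zip(ANCHOR_POSITIONS, variant):
                residues = _substitute(residues, pos, letter)
            chars = list(residues)
            for k in range(len(chars)):
                full = k + NUMBERING_OFFSET + 1
                if full in protected:
                    continue
                if rng.random() < background_mutation_rate:
                    chars[k] = letters[int(rng.integers(20))]
            rows.append((f"COH{i:04d}", "".join(chars)))
    return AlignedBlock.from_rows(rows)
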