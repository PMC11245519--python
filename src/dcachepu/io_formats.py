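"""Readers and writers for every external representation the pipeline touches.

Sequence data come in as FASTA, alignments as aligned FASTA or Stockholm,
domain-scanner hits as HMMER3 per-domain tables (domtblout) or plain TSV,
structures as the ATOM/HETATM subset of PDB, and annotations (taxonomy
lineage + domain architecture) as TSV.  All residue and column coordinates
are 1-based inclusive throughout the package, matching the residue naming
used for the reference receptor (e.g. Y121).

Parsing of FASTA/Stockholm is delegated to Biopython and PDB to gemmi;
this module only enforces the package's invariants on top (upper-casing,
'*' stripping, mapping non-canonical residues to 'X', gap normalisation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import gemmi
import pandas as pd
from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: canonical residue alphabet plus the unknown placeholder
ALPHABET = frozenset(AMINO_ACIDS) | {"X"}
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates the declared format."""


class DuplicateIdentifierError(FormatError):
    """Raised when a sequence collection contains repeated identifiers."""

    def __init__(self, duplicates: Sequence[str]):
        self.duplicates = list(duplicates)
        super().__init__(f"duplicate identifiers: {', '.join(self.duplicates)}")


def _clean_residues(raw: str) -> str:
    """Upper-case, strip stops, and map non-canonical letters to 'X'.

    Unknown or modified residues (B, Z, U, O, ...) never match a motif
    residue set, so collapsing them to 'X' is the conservative choice.
    """
    cleaned = []
    for ch in raw.upper():
        if ch == "*":
            continue
        cleaned.append(ch if ch in ALPHABET else "X")
    return "".join(cleaned)


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped amino-acid sequence with an accession-like identifier."""

    identifier: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.identifier!r} is empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.identifier!r} contains non-residue characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedBlock:
    """A multiple sequence alignment as (identifier, gapped row) pairs."""

    records: tuple[tuple[str, str], ...]
    column_count: int

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]]) -> "AlignedBlock":
        rows = [(rid, row.upper().replace(".", GAP)) for rid, row in rows]
        if not rows:
            raise FormatError("alignment has no rows")
        width = len(rows[0][1])
        for rid, row in rows:
            if len(row) != width:
                raise FormatError(
                    f"alignment row {rid!r} has length {len(row)}, expected {width}"
                )
        return cls(records=tuple(rows), column_count=width)

    @property
    def identifiers(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, identifier: str) -> str:
        for rid, row in self.records:
            if rid == identifier:
                return row
        raise KeyError(f"no alignment row {identifier!r}")

    def ungapped(self, identifier: str) -> SequenceRecord:
        return SequenceRecord(identifier, self.row(identifier).replace(GAP, ""))

    def column(self, col: int) -> str:
        """Residues of 1-based alignment column ``col`` across all rows."""
        if not 1 <= col <= self.column_count:
            raise IndexError(f"column {col} outside 1..{self.column_count}")
        return "".join(row[col - 1] for _, row in self.records)


@dataclass(frozen=True)
class DomainHit:
    """One row of a per-domain scanner table (envelope coordinates)."""

    protein_id: str
    domain_name: str
    env_start: int
    env_end: int
    e_value: float

    def __post_init__(self) -> None:
        if self.env_start < 1 or self.env_end < self.env_start:
            raise FormatError(
                f"bad envelope coordinates {self.env_start}..{self.env_end} "
                f"for {self.protein_id}/{self.domain_name}"
            )
        if self.e_value < 0 or math.isnan(self.e_value):
            raise FormatError(f"negative E-value {self.e_value} for {self.protein_id}")


class Atom(NamedTuple):
    serial: int
    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    x: float
    y: float
    z: float
    het_flag: bool


@dataclass(frozen=True)
class StructureModel:
    """Flat atom list from the ATOM/HETATM subset of a PDB file."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinates on atom {a.serial}")
            if a.residue_seq < 1:
                raise ValueError(f"non-positive residue_seq on atom {a.serial}")

    def het_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.het_flag]

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.het_flag]


@dataclass
class AnnotationTable:
    """Per-protein taxonomy lineage and domain-architecture annotation.

    ``lineage`` is an ordered list of rank names from superkingdom/domain
    downwards; ``architecture`` an ordered list of domain names.
    """

    rows: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=dict)

    def add(self, protein_id: str, lineage: Sequence[str], architecture: Sequence[str]) -> None:
        if protein_id in self.rows:
            raise DuplicateIdentifierError([protein_id])
        if not lineage:
            raise ValueError(f"empty lineage for {protein_id}")
        self.rows[protein_id] = (tuple(lineage), tuple(architecture))

    def lineage(self, protein_id: str) -> tuple[str, ...]:
        return self.rows[protein_id][0]

    def architecture(self, protein_id: str) -> tuple[str, ...]:
        return self.rows[protein_id][1]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.rows

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# readers


def read_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read ungapped protein sequences from a FASTA file.

    Order is preserved, '*' stops are stripped, lower-case is upper-cased
    and non-canonical letters become 'X'.  Duplicated identifiers and empty
    files are errors.
    """
    if format != "fasta":
        raise ValueError(f"unsupported sequence format {format!r}")
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(rec.id, _clean_residues(str(rec.seq)), rec.description)
        )
    if not records:
        raise FormatError(f"no sequences in {path}")
    seen: dict[str, int] = {}
    for r in records:
        seen[r.identifier] = seen.get(r.identifier, 0) + 1
    dups = [rid for rid, n in seen.items() if n > 1]
    if dups:
        raise DuplicateIdentifierError(dups)
    return records


def read_alignment(path: str | Path, format: str = "aligned-fasta") -> AlignedBlock:
    """Read a multiple sequence alignment ('.' gaps normalised to '-')."""
    if format == "aligned-fasta":
        rows = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    elif format == "stockholm":
        aln = AlignIO.read(str(path), "stockholm")
        rows = [(rec.id, str(rec.seq)) for rec in aln]
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    return AlignedBlock.from_rows(rows)


# 0-based field indices of the standard 23-column HMMER3 per-domain table
# (hmmscan orientation: target = domain model, query = protein).
_DOMTBL_TARGET, _DOMTBL_QUERY, _DOMTBL_IEVALUE = 0, 3, 12
_DOMTBL_ENV_FROM, _DOMTBL_ENV_TO = 19, 20


def read_domain_hits(path: str | Path, dialect: str = "tsv") -> list[DomainHit]:
    """Read per-domain hits with envelope coordinates.

    ``tsv`` expects five whitespace-separated columns
    (protein_id, domain_name, env_start, env_end, e_value); ``domtblout``
    the standard HMMER3 per-domain table (comment lines skipped, envelope
    columns and per-domain independent E-value used).  No E-value filtering
    is applied here.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "tsv":
                    pid, dom, start, end, ev = fields[:5]
                elif dialect == "domtblout":
                    if len(fields) < 22:
                        raise ValueError("too few columns for domtblout")
                    pid = fields[_DOMTBL_QUERY]
                    dom = fields[_DOMTBL_TARGET]
                    start = fields[_DOMTBL_ENV_FROM]
                    end = fields[_DOMTBL_ENV_TO]
                    ev = fields[_DOMTBL_IEVALUE]
                else:
                    raise ValueError(f"unsupported dialect {dialect!r}")
                hits.append(DomainHit(pid, dom, int(start), int(end), float(ev)))
            except (ValueError, IndexError, FormatError) as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    return hits


def filter_domain_hits(
    hits: Iterable[DomainHit], domain_name: str | None = None, e_value: float = 0.01
) -> list[DomainHit]:
    """Keep hits for ``domain_name`` passing the E-value threshold (default 0.01)."""
    return [
        h
        for h in hits
        if h.e_value <= e_value and (domain_name is None or h.domain_name == domain_name)
    ]


def extract_domain(seq: SequenceRecord, hit: DomainHit) -> SequenceRecord:
    """Cut the envelope region of a domain hit out of its protein sequence."""
    if hit.env_end > len(seq):
        raise FormatError(
            f"envelope {hit.env_start}..{hit.env_end} exceeds length of {seq.identifier}"
        )
    region = seq.residues[hit.env_start - 1 : hit.env_end]
    return SequenceRecord(
        f"{seq.identifier}/{hit.env_start}-{hit.env_end}", region, seq.description
    )


def read_structure(path: str | Path) -> StructureModel:
    """Read the ATOM/HETATM subset of a PDB file into a flat atom list."""
    st = gemmi.read_pdb(str(path))
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H"
                for atom in residue:
                    atoms.append(
                        Atom(
                            serial=atom.serial,
                            atom_name=atom.name,
                            element=atom.element.name.upper(),
                            residue_name=residue.name,
                            chain_id=chain.name,
                            residue_seq=residue.seqid.num,
                            x=atom.pos.x,
                            y=atom.pos.y,
                            z=atom.pos.z,
                            het_flag=het,
                        )
                    )
        break  # first model only
    if not any(not a.het_flag for a in atoms):
        raise FormatError(f"no ATOM records in {path}")
    return StructureModel(tuple(atoms))


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a TSV of protein_id, ';'-separated lineage, '|'-separated architecture."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"protein_id", "lineage", "architecture"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation table must have columns {sorted(required)}")
    table = AnnotationTable()
    for _, row in df.iterrows():
        lineage = [t for t in row["lineage"].split(";") if t]
        arch = [t for t in row["architecture"].split("|") if t]
        table.add(row["protein_id"], lineage, arch)
    return table


# ---------------------------------------------------------------------------
# writers


def write_sequences(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.identifier
            if rec.description and rec.description != rec.identifier:
                header = rec.description if rec.description.startswith(rec.identifier) else f"{rec.identifier} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_alignment(block: AlignedBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in block.records:
            fh.write(f">{rid}\n{row}\n")


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    rows = [
        {"protein_id": pid, "lineage": ";".join(lin), "architecture": "|".join(arch)}
        for pid, (lin, arch) in table.rows.items()
    ]
    pd.DataFrame(rows, columns=["protein_id", "lineage", "architecture"]).to_csv(
        path, sep="\t", index=False
    )


def _as_mapping(report) -> Mapping:
    if hasattr(report, "to_mapping"):
        return report.to_mapping()
    if isinstance(report, Mapping):
        return report
    raise TypeError(f"cannot serialise report of type {type(report).__name__}")


def write_report(report, path: str | Path, format: str = "tsv") -> None:
    """Write a tabular or mapping-like report as TSV or JSON.

    Values round-trip at full stored precision (floats via ``repr``).
    """
    path = Path(path)
    if isinstance(report, pd.DataFrame):
        if format == "tsv":
            report.to_csv(path, sep="\t", index=False, float_format=None)
        elif format == "json":
            path.write_text(report.to_json(orient="records", double_precision=15) + "\n")
        else:
            raise ValueError(f"unsupported report format {format!r}")
        return
    mapping = _as_mapping(report)
    if format == "json":
        path.write_text(json.dumps(mapping, indent=2, default=float) + "\n")
    elif format == "tsv":
        keys = list(mapping)
        with open(path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            fh.write("\t".join(repr(mapping[k]) if isinstance(mapping[k], float) else str(mapping[k]) for k in keys) + "\n")
    else:
        raise ValueError(f"unsupported report format {format!r}")


def read_report(path: str | Path, format: str = "tsv"):
    """Inverse of :func:`write_report` (DataFrame for TSV, dict for JSON)."""
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return json.loads(Path(path).read_text())
    raise ValueError(f"unsupported report format {format!r}")
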