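"""Anchoring sequences to the reference domain and tracking motif positions.

The motif is defined in the residue numbering of the reference receptor
(full-length numbering, e.g. Y121), while candidate sequences arrive either
as rows of a multiple sequence alignment or as bare domain sequences.  This
module provides:

* a deterministic global/semi-global pairwise aligner (affine gaps,
  BLOSUM62 by default) for anchoring a single query to the reference;
* position tracking — mapping reference residue positions to alignment
  columns and reading off the residue every other row carries there;
* per-column conservation profiles;
* the gap-based column trimming rule used before phylogenetic analysis:
  drop columns with a gap fraction of 10% or more, unless that would leave
  fewer than 60% of the columns, in which case the 60% of columns with the
  fewest gaps are kept.

Gap convention for the aligner: a gap run of length L costs
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Mapping

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import ALPHABET, GAP, AlignedBlock, SequenceRecord

NEG = float("-inf")


# ---------------------------------------------------------------------------
# reference anchoring


@dataclass(frozen=True)
class ReferenceAnchor:
    """The reference domain plus the motif positions tracked on it.

    ``anchor_positions`` and ``companion_position`` are in full-length
    reference numbering; ``numbering_offset`` converts between the bundled
    domain sequence (1-based domain index) and that numbering:
    ``full_position = domain_index + numbering_offset``.
    """

    reference_record: SequenceRecord
    anchor_positions: tuple[int, ...] = (121, 129, 140, 167, 169)
    companion_position: int = 141
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if list(self.anchor_positions) != sorted(set(self.anchor_positions)):
            raise ValueError("anchor positions must be strictly increasing")
        for p in (*self.anchor_positions, self.companion_position):
            self.domain_index(p)

    def domain_index(self, full_position: int) -> int:
        idx = full_position - self.numbering_offset
        if not 1 <= idx <= len(self.reference_record):
            raise ValueError(
                f"position {full_position} outside the reference domain "
                f"({self.numbering_offset + 1}..{self.numbering_offset + len(self.reference_record)})"
            )
        return idx

    def residue_at(self, full_position: int) -> str:
        return self.reference_record.residues[self.domain_index(full_position) - 1]


@dataclass(frozen=True)
class PairwiseAlignment:
    ref_id: str
    query_id: str
    ref_gapped: str
    query_gapped: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_gapped) != len(self.query_gapped):
            raise ValueError("gapped rows must have equal length")

    def as_block(self) -> AlignedBlock:
        return AlignedBlock.from_rows(
            [(self.ref_id, self.ref_gapped), (self.query_id, self.query_gapped)]
        )


# ---------------------------------------------------------------------------
# pairwise aligner (Gotoh, deterministic traceback)


def _score_lookup(matrix_name: str):
    mat = substitution_matrices.load(matrix_name)
    alpha = mat.alphabet

    def score(a: str, b: str) -> float:
        return float(mat[alpha.index(a), alpha.index(b)])

    return score


def align_to_reference(
    query: SequenceRecord,
    anchor: ReferenceAnchor | SequenceRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    semi_global: bool = True,
) -> PairwiseAlignment:
    """Optimal pairwise alignment of ``query`` to the reference domain.

    Affine gaps (run of length L costs open + (L-1)*extend).  In
    semi-global mode terminal gaps in the *query row* are free, so a query
    fragment may land anywhere on the reference without penalty; global
    mode penalises all terminal gaps.  Ties are broken deterministically:
    substitution over gap opening, then gap-in-reference over gap-in-query.
    """
    ref = anchor.reference_record if isinstance(anchor, ReferenceAnchor) else anchor
    x, y = ref.residues, query.residues
    for seq, name in ((x, ref.identifier), (y, query.identifier)):
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(f"{name!r} contains characters outside the alphabet: {sorted(bad)}")
    m, n = len(x), len(y)
    s = _score_lookup(matrix)

    # state matrices: M substitution, X gap in query row (consumes ref),
    # Y gap in ref row (consumes query)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    # pointers: 0=M, 1=Y, 2=X, 3=start
    Mp = [[0] * (n + 1) for _ in range(m + 1)]
    Xp = [[0] * (n + 1) for _ in range(m + 1)]
    Yp = [[0] * (n + 1) for _ in range(m + 1)]

    M[0][0] = 0.0
    for j in range(1, n + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
        Yp[0][j] = 1
    for i in range(1, m + 1):
        if semi_global:
            M[i][0] = 0.0  # free leading reference overhang
            Mp[i][0] = 3
        else:
            X[i][0] = -(gap_open + (i - 1) * gap_extend)
            Xp[i][0] = 2

    for i in range(1, m + 1):
        xi = x[i - 1]
        for j in range(1, n + 1):
            sub = s(xi, y[j - 1])
            # order encodes tie preference: M, then Y (ref-gap), then X
            cands = (M[i - 1][j - 1], Y[i - 1][j - 1], X[i - 1][j - 1])
            k = max(range(3), key=lambda t: cands[t])
            M[i][j] = cands[k] + sub
            Mp[i][j] = k

            cx = (M[i - 1][j] - gap_open, Y[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            k = max(range(3), key=lambda t: cx[t])
            X[i][j] = cx[k]
            Xp[i][j] = k

            cy = (M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend, X[i][j - 1] - gap_open)
            k = max(range(3), key=lambda t: cy[t])
            Y[i][j] = cy[k]
            Yp[i][j] = k

    if semi_global:
        end_i, end_state, best = m, 0, NEG
        for i in range(m + 1):
            # state order encodes the tie preference (M, then Y, then X);
            # among equal-scoring ends prefer the largest reference extent
            for state, val in ((0, M[i][n]), (1, Y[i][n]), (2, X[i][n])):
                if val > best or (val == best and i > end_i):
                    best, end_i, end_state = val, i, state
        score = best
    else:
        vals = (M[m][n], Y[m][n], X[m][n])
        end_state = max(range(3), key=lambda t: vals[t])
        end_i, score = m, vals[end_state]

    # traceback
    ref_row: list[str] = []
    qry_row: list[str] = []
    for i in range(m, end_i, -1):  # free trailing reference overhang
        ref_row.append(x[i - 1])
        qry_row.append(GAP)
    i, j, state = end_i, n, end_state
    while True:
        if state == 0:
            if i == 0 and j == 0:
                break
            if Mp[i][j] == 3 or (j == 0 and semi_global and M[i][j] == 0.0 and i >= 0):
                # reached a free leading-overhang start point
                for k in range(i, 0, -1):
                    ref_row.append(x[k - 1])
                    qry_row.append(GAP)
                break
            ref_row.append(x[i - 1])
            qry_row.append(y[j - 1])
            state = Mp[i][j]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
        elif state == 1:  # gap in reference row
            ref_row.append(GAP)
            qry_row.append(y[j - 1])
            state = Yp[i][j]
            j -= 1
            if i == 0 and j == 0:
                break
        else:  # gap in query row
            ref_row.append(x[i - 1])
            qry_row.append(GAP)
            state = Xp[i][j]
            i -= 1
            if i == 0 and j == 0:
                break

    return PairwiseAlignment(
        ref_id=ref.identifier,
        query_id=query.identifier,
        ref_gapped="".join(reversed(ref_row)),
        query_gapped="".join(reversed(qry_row)),
        score=score,
    )


# ---------------------------------------------------------------------------
# position tracking


@dataclass
class ColumnMap:
    """Mapping of reference positions to alignment columns and row residues.

    ``columns`` maps a full-length reference position to its 1-based
    alignment column (None if the reference row does not reach it);
    ``residues``/``query_indices`` give, per sequence, the letter (or '-')
    and the 1-based ungapped index at that column.
    """

    reference_id: str
    columns: dict[int, int | None]
    residues: dict[str, dict[int, str]]
    query_indices: dict[str, dict[int, int | None]]


def map_positions(
    source: PairwiseAlignment | AlignedBlock,
    anchor: ReferenceAnchor,
    reference_id: str | None = None,
    positions: Iterable[int] | None = None,
) -> ColumnMap:
    """Track reference positions through an alignment.

    ``positions`` defaults to the anchor positions plus the companion
    aromatic.  For each position the column holding that reference residue
    is located on the reference row; every other row contributes the
    residue (or gap) it carries in that column.
    """
    if isinstance(source, PairwiseAlignment):
        block = source.as_block()
        reference_id = source.ref_id
    else:
        block = source
        if reference_id is None:
            reference_id = anchor.reference_record.identifier
    ref_row = block.row(reference_id)
    pos_list = list(positions) if positions is not None else [
        *anchor.anchor_positions,
        anchor.companion_position,
    ]

    # column of the k-th non-gap residue of the reference row
    residue_to_col: list[int] = [
        col for col, ch in enumerate(ref_row, start=1) if ch != GAP
    ]
    columns: dict[int, int | None] = {}
    for p in pos_list:
        k = anchor.domain_index(p)  # raises if beyond the reference
        columns[p] = residue_to_col[k - 1] if k <= len(residue_to_col) else None

    residues: dict[str, dict[int, str]] = {}
    query_indices: dict[str, dict[int, int | None]] = {}
    for rid, row in block.records:
        res_p: dict[int, str] = {}
        idx_p: dict[int, int | None] = {}
        # prefix counts of non-gap characters for 1-based ungapped indices
        counts = np.cumsum([ch != GAP for ch in row])
        for p, col in columns.items():
            if col is None:
                res_p[p] = GAP
                idx_p[p] = None
                continue
            ch = row[col - 1]
            res_p[p] = ch
            idx_p[p] = int(counts[col - 1]) if ch != GAP else None
        residues[rid] = res_p
        query_indices[rid] = idx_p
    return ColumnMap(reference_id, columns, residues, query_indices)


# ---------------------------------------------------------------------------
# conservation


@dataclass
class ConservationProfile:
    """Per-column residue frequencies and gap fractions of an alignment."""

    column_count: int
    n_rows: int
    frequencies: list[dict[str, float]]  # over all rows, gaps excluded
    gap_fraction: np.ndarray

    def nongap_frequencies(self, col: int) -> dict[str, float]:
        """Residue frequencies among non-gap rows of 1-based column ``col``."""
        freqs = self.frequencies[col - 1]
        nongap = 1.0 - float(self.gap_fraction[col - 1])
        if nongap <= 0:
            return {}
        return {r: f / nongap for r, f in freqs.items()}

    def conserved(self, col: int, residues: Iterable[str], tau: float = 0.90) -> bool:
        """True when residues of ``residues`` cover ≥ tau of non-gap rows."""
        freqs = self.nongap_frequencies(col)
        return sum(freqs.get(r, 0.0) for r in set(residues)) >= tau


def conservation_profile(msa: AlignedBlock) -> ConservationProfile:
    """Empirical per-column residue frequency vectors and gap fractions."""
    if len(msa.records) < 2:
        raise ValueError("conservation requires at least 2 rows")
    arr = np.array([list(row) for _, row in msa.records])
    n = arr.shape[0]
    freqs: list[dict[str, float]] = []
    gapf = np.zeros(msa.column_count)
    for c in range(msa.column_count):
        col = arr[:, c]
        letters, counts = np.unique(col, return_counts=True)
        d: dict[str, float] = {}
        for letter, cnt in zip(letters, counts):
            if letter == GAP:
                gapf[c] = cnt / n
            else:
                d[str(letter)] = cnt / n
        freqs.append(d)
    return ConservationProfile(msa.column_count, n, freqs, gapf)


# ---------------------------------------------------------------------------
# trimming


@dataclass
class TrimResult:
    kept_columns: list[int]  # original 1-based column indices, ascending
    trimmed_block: AlignedBlock


def trim_alignment(
    msa: AlignedBlock, gap_threshold: float = 0.10, keep_fraction: float = 0.60
) -> TrimResult:
    """Remove gappy columns, with a floor on how many columns survive.

    Columns whose gap fraction is >= ``gap_threshold`` are removed, unless
    that would leave fewer than ``keep_fraction`` of the columns; in that
    case the ``ceil(keep_fraction * column_count)`` columns with the
    smallest gap fraction are kept (ties broken by lower column index).
    """
    if not msa.records:
        raise ValueError("empty alignment")
    n_cols = msa.column_count
    arr = np.array([list(row) for _, row in msa.records])
    gapf = (arr == GAP).mean(axis=0)

    kept = [c + 1 for c in range(n_cols) if gapf[c] < gap_threshold]
    min_keep = ceil(keep_fraction * n_cols - 1e-9)
    if len(kept) < keep_fraction * n_cols - 1e-9:
        order = sorted(range(n_cols), key=lambda c: (gapf[c], c))
        kept = sorted(c + 1 for c in order[:min_keep])

    rows = [(rid, "".join(row[c - 1] for c in kept)) for rid, row in msa.records]
    return TrimResult(kept, AlignedBlock.from_rows(rows))
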