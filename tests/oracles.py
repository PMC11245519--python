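"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by exhaustive enumeration or by a direct
transcription of the stated rule, sharing no code with the implementation
it checks.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = _BLOSUM.alphabet


def blosum(a: str, b: str) -> float:
    return float(_BLOSUM[_ALPHA.index(a), _ALPHA.index(b)])


def brute_force_align_score(
    x: str,
    y: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    semi_global: bool = True,
) -> float:
    """Best affine-gap alignment score by depth-first path enumeration.

    Enumerates every monotone alignment path through the (len(x), len(y))
    lattice, scoring gap runs as open + (run-1)*extend.  In semi-global
    mode, runs of gap-in-query (reference residues over '-') at the very
    start or very end are free.
    """
    m, n = len(x), len(y)
    best = -math.inf

    def go(i: int, j: int, state: str, score: float, leading: bool) -> None:
        nonlocal best
        if i == m and j == n:
            if score > best:
                best = score
            return
        if i < m and j < n:  # substitution
            go(i + 1, j + 1, "M", score + blosum(x[i], y[j]), False)
        if i < m:  # gap in query row (consumes reference)
            if semi_global and (leading or j == n):
                go(i + 1, j, "Xf", score, leading and j == 0)
            else:
                cost = gap_extend if state == "X" else gap_open
                go(i + 1, j, "X", score - cost, False)
        if j < n:  # gap in reference row (consumes query)
            cost = gap_extend if state == "Y" else gap_open
            go(i, j + 1, "Y", score - cost, False)

    go(0, 0, "start", 0.0, True)
    return best


def brute_force_contacts(atoms, ligand_name: str, cutoff: float) -> dict[tuple, float]:
    """All-pairs heavy-atom contact map: residue key -> min distance."""
    lig = [a for a in atoms if a.het_flag and a.residue_name == ligand_name and a.element not in {"H", "D"}]
    prot = [a for a in atoms if not a.het_flag and a.element not in {"H", "D"}]
    out: dict[tuple, float] = {}
    for p in prot:
        for l in lig:
            d = math.dist((p.x, p.y, p.z), (l.x, l.y, l.z))
            key = (p.chain_id, p.residue_seq, p.residue_name)
            if d < out.get(key, math.inf):
                out[key] = d
    return {k: v for k, v in out.items() if v <= cutoff}


def hand_trim(rows: list[str], gap_threshold: float = 0.10, keep_fraction: float = 0.60) -> list[int]:
    """The column-trimming rule transcribed directly: returns kept 1-based columns."""
    n_cols = len(rows[0])
    n_rows = len(rows)
    gapf = [sum(r[c] == "-" for r in rows) / n_rows for c in range(n_cols)]
    kept = [c + 1 for c in range(n_cols) if gapf[c] < gap_threshold]
    if len(kept) < keep_fraction * n_cols - 1e-9:
        want = math.ceil(keep_fraction * n_cols - 1e-9)
        ranked = sorted(range(n_cols), key=lambda c: (gapf[c], c))
        kept = sorted(c + 1 for c in ranked[:want])
    return kept


def brute_force_motif_scan(seq: str, motif, require_companion: bool = True):
    """Exhaustive nested-loop tuple search; returns (matched, tuple or None).

    Independently transcribes the motif rule: residue-set membership,
    spacing windows on residues strictly between consecutive positions,
    optional companion residue, minimal total |deviation| then leftmost.
    """
    sets = [allowed for _, allowed in motif.positions]
    windows = motif.spacings
    centers = motif.centers
    comp = motif.companion
    comp_idx = motif.names.index(comp.anchor_name) if comp is not None else None
    n = len(seq)
    best_key, best_tup = None, None
    for p1 in range(1, n + 1):
        if seq[p1 - 1] not in sets[0]:
            continue
        for p2 in range(p1 + windows[0][0] + 1, min(p1 + windows[0][1] + 1, n) + 1):
            if seq[p2 - 1] not in sets[1]:
                continue
            for p3 in range(p2 + windows[1][0] + 1, min(p2 + windows[1][1] + 1, n) + 1):
                if seq[p3 - 1] not in sets[2]:
                    continue
                for p4 in range(p3 + windows[2][0] + 1, min(p3 + windows[2][1] + 1, n) + 1):
                    if seq[p4 - 1] not in sets[3]:
                        continue
                    for p5 in range(p4 + windows[3][0] + 1, min(p4 + windows[3][1] + 1, n) + 1):
                        if seq[p5 - 1] not in sets[4]:
                            continue
                        tup = (p1, p2, p3, p4, p5)
                        if comp is not None and require_companion:
                            cpos = tup[comp_idx] + comp.offset
                            if not (1 <= cpos <= n and seq[cpos - 1] in comp.residues):
                                continue
                        gaps = [b - a - 1 for a, b in zip(tup, tup[1:])]
                        key = (sum(abs(g - c) for g, c in zip(gaps, centers)), tup)
                        if best_key is None or key < best_key:
                            best_key, best_tup = key, tup
    return best_tup is not None, best_tup


def column_frequency_counts(rows: list[str], col: int) -> tuple[dict[str, int], int]:
    """Direct per-column counting: (residue counts, gap count), 1-based col."""
    counts: dict[str, int] = {}
    gaps = 0
    for r in rows:
        ch = r[col - 1]
        if ch == "-":
            gaps += 1
        else:
            counts[ch] = counts.get(ch, 0) + 1
    return counts, gaps
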