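"""The purine-binding (dCache_1PU) motif: definition, scanning, variants.

The motif is five ordered positions with allowed residue sets and bounded
spacings between consecutive positions (counting residues strictly in
between).  The default object encodes the purine-binding motif of dCache_1
sensor domains: P1 {Y,F}, P2 {R,K,H}, P3 {W,F}, P4 {F,Y}, P5 {N,D}, with
centre gaps 7, 10, 26, 1 derived from the reference residues
Y121/R129/W140/F167/D169, a tolerance of ±4 residues per gap (±1 for the
adjacent P4→P5 pair), and a companion aromatic {F,Y,W} immediately after
P3 (the F141 position) that plays a structural rather than
ligand-contacting role.

Two scanning modes exist: *aligned* reads the residues each sequence
carries at the reference anchor columns of a shared alignment (no spacing
tolerance needed); *linear* searches a bare sequence for position tuples
satisfying the residue sets and spacing windows, reporting the tuple with
minimal total spacing deviation.  The concatenated residues at P1..P5 form
the motif *variant* string (e.g. "YRWFN").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .align_map import ColumnMap, ConservationProfile, ReferenceAnchor
from .io_formats import GAP, SequenceRecord


@dataclass(frozen=True)
class Companion:
    """A structurally required residue at a fixed offset from a motif position."""

    anchor_name: str = "P3"
    offset: int = 1
    residues: frozenset[str] = frozenset("FYW")


@dataclass
class MotifDefinition:
    """Ordered motif positions, allowed residue sets and spacing windows.

    ``spacings`` bound the number of residues strictly between consecutive
    positions; ``centers`` are the reference gaps from which spacing
    deviations are measured.  ``reference_positions`` (optional) ties each
    position to a full-length reference residue index for aligned-mode
    scanning.
    """

    positions: list[tuple[str, frozenset[str]]]
    spacings: list[tuple[int, int]]
    centers: list[int] | None = None
    companion: Companion | None = Companion()
    reference_positions: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.spacings) != len(self.positions) - 1:
            raise ValueError("need one spacing window per consecutive position pair")
        for lo, hi in self.spacings:
            if lo < 0 or hi < lo:
                raise ValueError(f"bad spacing window ({lo}, {hi})")
        for name, residues in self.positions:
            if not residues:
                raise ValueError(f"empty residue set at {name}")
        if self.centers is None:
            self.centers = [(lo + hi) // 2 for lo, hi in self.spacings]
        if self.reference_positions is not None and len(self.reference_positions) != len(
            self.positions
        ):
            raise ValueError("reference_positions must match positions")

    @classmethod
    def default(cls) -> "MotifDefinition":
        """The dCache_1PU purine-binding motif."""
        centers = [7, 10, 26, 1]
        tols = [4, 4, 4, 1]
        return cls(
            positions=[
                ("P1", frozenset("YF")),
                ("P2", frozenset("RKH")),
                ("P3", frozenset("WF")),
                ("P4", frozenset("FY")),
                ("P5", frozenset("ND")),
            ],
            spacings=[(max(0, c - t), c + t) for c, t in zip(centers, tols)],
            centers=centers,
            companion=Companion(),
            reference_positions=[121, 129, 140, 167, 169],
        )

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.positions]

    def companion_reference_position(self) -> int | None:
        """Full-length reference index of the companion residue, if tied."""
        if self.companion is None or self.reference_positions is None:
            return None
        k = self.names.index(self.companion.anchor_name)
        return self.reference_positions[k] + self.companion.offset

    # -- YAML round-trip (CLI motif files) ---------------------------------
    def to_yaml(self) -> str:
        doc = {
            "positions": [
                {"name": name, "residues": "".join(sorted(res))}
                for name, res in self.positions
            ],
            "spacings": [{"min": lo, "max": hi} for lo, hi in self.spacings],
            "centers": list(self.centers or []),
        }
        if self.companion is not None:
            doc["companion"] = {
                "anchor": self.companion.anchor_name,
                "offset": self.companion.offset,
                "residues": "".join(sorted(self.companion.residues)),
            }
        if self.reference_positions is not None:
            doc["reference_positions"] = list(self.reference_positions)
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "MotifDefinition":
        doc = yaml.safe_load(text)
        companion = None
        if "companion" in doc:
            c = doc["companion"]
            companion = Companion(c["anchor"], c["offset"], frozenset(c["residues"]))
        return cls(
            positions=[(p["name"], frozenset(p["residues"])) for p in doc["positions"]],
            spacings=[(s["min"], s["max"]) for s in doc["spacings"]],
            centers=doc.get("centers") or None,
            companion=companion,
            reference_positions=doc.get("reference_positions"),
        )


@dataclass
class MotifMatch:
    """Result of scanning one sequence for the motif."""

    matched: bool
    variant: str | None = None
    positions_in_query: tuple[int, ...] = ()
    spacing_deviation: tuple[int, ...] = ()
    companion_ok: bool = True
    reason: str | None = None


@dataclass
class ScanParams:
    mode: str = "linear"  # {"aligned", "linear"}
    require_companion: bool = True
    max_candidates_reported: int = 1

    def __post_init__(self) -> None:
        if self.mode not in {"aligned", "linear"}:
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.max_candidates_reported < 1:
            raise ValueError("max_candidates_reported must be >= 1")


# ---------------------------------------------------------------------------
# derivation from conservation + contacts


def derive_motif(
    profile: ConservationProfile,
    contact_positions: Sequence[int],
    column_map: ColumnMap,
    anchor: ReferenceAnchor,
    tau: float = 0.90,
    tau_res: float = 0.05,
    max_set_size: int = 4,
    tolerance: int = 4,
    adjacent_tolerance: int = 1,
) -> MotifDefinition:
    """Derive a motif from ligand contacts and alignment conservation.

    A contact position survives when the most frequent residues of its
    column (each with non-gap frequency >= ``tau_res``, at most
    ``max_set_size`` of them) jointly cover >= ``tau`` of non-gap rows;
    the allowed set is those residues ordered by frequency.  Spacings are
    the reference gaps with ``tolerance`` slack (``adjacent_tolerance``
    for centre gaps of 2 or fewer).
    """
    kept: list[tuple[int, list[str]]] = []
    for pos in sorted(contact_positions):
        col = column_map.columns.get(pos)
        if col is None:
            continue
        freqs = profile.nongap_frequencies(col)
        ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
        allowed = [r for r, f in ranked if f >= tau_res][:max_set_size]
        if allowed and sum(freqs[r] for r in allowed) >= tau:
            kept.append((pos, allowed))
    if len(kept) < 2:
        raise ValueError("no motif derivable: fewer than two conserved contact positions")

    ref_positions = [pos for pos, _ in kept]
    centers = [b - a - 1 for a, b in zip(ref_positions, ref_positions[1:])]
    spacings = []
    for c in centers:
        t = adjacent_tolerance if c <= 2 else tolerance
        spacings.append((max(0, c - t), c + t))
    positions = [
        (f"P{i + 1}", frozenset(allowed)) for i, (_, allowed) in enumerate(kept)
    ]
    # companion aromatic immediately after the position matching the
    # reference structural aromatic (companion_position - 1 == some anchor)
    companion = None
    comp_pred = anchor.companion_position - 1
    if comp_pred in ref_positions:
        companion = Companion(
            anchor_name=f"P{ref_positions.index(comp_pred) + 1}",
            offset=anchor.companion_position - comp_pred,
            residues=frozenset("FYW"),
        )
    return MotifDefinition(
        positions=positions,
        spacings=spacings,
        centers=centers,
        companion=companion,
        reference_positions=ref_positions,
    )


# ---------------------------------------------------------------------------
# scanning


def scan_aligned(
    column_map: ColumnMap, motif: MotifDefinition, params: ScanParams | None = None
) -> dict[str, MotifMatch]:
    """Classify every sequence of a column map against the motif.

    A sequence matches when every motif position maps to a non-gap residue
    of the allowed set (and, when required, the companion column holds an
    allowed aromatic).  Requires ``motif.reference_positions``.
    """
    params = params or ScanParams(mode="aligned")
    if motif.reference_positions is None:
        raise ValueError("aligned scanning needs a motif tied to reference positions")
    comp_pos = motif.companion_reference_position()
    results: dict[str, MotifMatch] = {}
    for seq_id, res_p in column_map.residues.items():
        deleted = [p for p in motif.reference_positions if column_map.columns.get(p) is None]
        if deleted:
            results[seq_id] = MotifMatch(False, reason="reference position deleted")
            continue
        letters = [res_p[p] for p in motif.reference_positions]
        ok = all(
            ch != GAP and ch in allowed
            for ch, (_, allowed) in zip(letters, motif.positions)
        )
        companion_ok = True
        if motif.companion is not None and comp_pos is not None:
            comp_ch = res_p.get(comp_pos, GAP)
            companion_ok = comp_ch != GAP and comp_ch in motif.companion.residues
            if params.require_companion:
                ok = ok and companion_ok
        if not ok:
            results[seq_id] = MotifMatch(False, companion_ok=companion_ok)
            continue
        qidx = column_map.query_indices[seq_id]
        results[seq_id] = MotifMatch(
            matched=True,
            variant="".join(letters),
            positions_in_query=tuple(qidx[p] for p in motif.reference_positions),
            spacing_deviation=tuple(0 for _ in motif.spacings),
            companion_ok=companion_ok,
        )
    return results


def _candidate_tuples(seq: str, motif: MotifDefinition) -> Iterable[tuple[int, ...]]:
    """All 1-based position tuples satisfying residue sets and spacings."""
    sets = [allowed for _, allowed in motif.positions]
    n = len(seq)
    first = [i for i in range(1, n + 1) if seq[i - 1] in sets[0]]

    def extend(prefix: tuple[int, ...], k: int):
        if k == len(sets):
            yield prefix
            return
        lo, hi = motif.spacings[k - 1]
        prev = prefix[-1]
        for pos in range(prev + lo + 1, min(prev + hi + 1, n) + 1):
            if seq[pos - 1] in sets[k]:
                yield from extend(prefix + (pos,), k + 1)

    for p1 in first:
        yield from extend((p1,), 1)


def scan_linear(
    seq: SequenceRecord, motif: MotifDefinition, params: ScanParams | None = None
) -> MotifMatch:
    """Search a bare sequence for the motif with spacing windows.

    Among admissible position tuples the one with minimal total absolute
    spacing deviation is reported (ties: leftmost positions).  When the
    companion is required, the residue at companion offset from its anchor
    position must belong to the companion set.
    """
    params = params or ScanParams(mode="linear")
    s = seq.residues
    centers = motif.centers or []
    comp = motif.companion
    comp_idx = motif.names.index(comp.anchor_name) if comp is not None else -1

    best: tuple | None = None
    for tup in _candidate_tuples(s, motif):
        companion_ok = True
        if comp is not None:
            cpos = tup[comp_idx] + comp.offset
            companion_ok = 1 <= cpos <= len(s) and s[cpos - 1] in comp.residues
            if params.require_companion and not companion_ok:
                continue
        gaps = [b - a - 1 for a, b in zip(tup, tup[1:])]
        devs = tuple(g - c for g, c in zip(gaps, centers))
        total = sum(abs(d) for d in devs)
        key = (total, tup)
        if best is None or key < best[0]:
            best = (key, tup, devs, companion_ok)
    if best is None:
        return MotifMatch(False)
    _, tup, devs, companion_ok = best
    return MotifMatch(
        matched=True,
        variant="".join(s[p - 1] for p in tup),
        positions_in_query=tup,
        spacing_deviation=devs,
        companion_ok=companion_ok,
    )


def variant_table(
    matches: dict[str, MotifMatch] | Iterable[tuple[str, MotifMatch]]
) -> pd.DataFrame:
    """One row per sequence: id, variant ('-' when unmatched), matched flag."""
    items = matches.items() if isinstance(matches, dict) else matches
    rows = [
        {
            "protein_id": sid,
            "variant": m.variant if m.matched else "-",
            "matched": bool(m.matched),
        }
        for sid, m in items
    ]
    return pd.DataFrame(rows, columns=["protein_id", "variant", "matched"])
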