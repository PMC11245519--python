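import numpy as np
import pytest

from dcachepu.align_map import conservation_profile, map_positions, align_to_reference
from dcachepu.io_formats import SequenceRecord
from dcachepu.motif_model import (
    Companion,
    MotifDefinition,
    ScanParams,
    derive_motif,
    scan_aligned,
    scan_linear,
    variant_table,
)
from dcachepu.reference_synthetic import (
    CONTACT_POSITIONS,
    synthetic_cohort_alignment,
    synthetic_receptor_panel,
)

from oracles import brute_force_motif_scan

LETTERS = list("ACDEFGHIKLMNPQRSTVWY")


def plant(variant, gaps, companion="F", flank=30, background="A"):
    """A sequence with a single planted motif instance on a neutral background.

    The companion aromatic occupies the first in-between residue after P3.
    """
    return "".join(
        [
            background * flank,
            variant[0], background * gaps[0],
            variant[1], background * gaps[1],
            variant[2], companion + background * (gaps[2] - 1),
            variant[3], background * gaps[3],
            variant[4],
            background * flank,
        ]
    )


class TestDefinition:
    def test_default_windows_from_reference_spacings(self, default_motif):
        assert default_motif.centers == [7, 10, 26, 1]
        assert default_motif.spacings == [(3, 11), (6, 14), (22, 30), (0, 2)]

    def test_yaml_roundtrip(self, default_motif):
        back = MotifDefinition.from_yaml(default_motif.to_yaml())
        assert back.positions == default_motif.positions
        assert back.spacings == default_motif.spacings
        assert back.companion == default_motif.companion
        assert back.reference_positions == default_motif.reference_positions

    def test_bad_spacing_count_rejected(self):
        with pytest.raises(ValueError):
            MotifDefinition(
                positions=[("P1", frozenset("Y")), ("P2", frozenset("R"))], spacings=[]
            )


class TestScanLinear:
    def test_planted_motif_at_center_spacings(self, default_motif):
        seq = plant("YRWFN", default_motif.centers)
        m = scan_linear(SequenceRecord("s", seq), default_motif)
        assert m.matched and m.variant == "YRWFN"
        assert m.spacing_deviation == (0, 0, 0, 0)

    def test_mutated_p2_unmatched(self, default_motif):
        seq = plant("YRWFN", default_motif.centers).replace("R", "A")
        m = scan_linear(SequenceRecord("s", seq), default_motif)
        assert not m.matched

    def test_companion_required_by_default(self, default_motif):
        seq = plant("YRWFN", default_motif.centers, companion="A")
        assert not scan_linear(SequenceRecord("s", seq), default_motif).matched
        relaxed = ScanParams(mode="linear", require_companion=False)
        assert scan_linear(SequenceRecord("s", seq), default_motif, relaxed).matched

    def test_matches_exhaustive_tuple_oracle_on_random_sequences(self, default_motif):
        """Match decisions and reported tuples equal brute-force enumeration."""
        rng = np.random.default_rng(3)
        n_matched = 0
        for _ in range(60):
            seq = "".join(rng.choice(LETTERS, size=150))
            got = scan_linear(SequenceRecord("s", seq), default_motif)
            want_matched, want_tup = brute_force_motif_scan(seq, default_motif)
            assert got.matched == want_matched
            if want_matched:
                assert got.positions_in_query == want_tup
                n_matched += 1
        assert n_matched > 0  # the oracle comparison saw real matches

    def test_zero_tolerance_singletons_is_literal_string_match(self):
        motif = MotifDefinition(
            positions=[("P1", frozenset("Y")), ("P2", frozenset("R")), ("P3", frozenset("W"))],
            spacings=[(2, 2), (0, 0)],
            companion=None,
        )
        # pattern is literally Y..RW with exactly 2 residues between P1 and P2
        hit = SequenceRecord("a", "GGYAARWGG")
        miss = SequenceRecord("b", "GGYAAARWG")
        assert scan_linear(hit, motif).matched
        assert scan_linear(hit, motif).positions_in_query == (3, 6, 7)
        assert not scan_linear(miss, motif).matched

    def test_widening_sets_or_windows_is_monotone(self, default_motif, rng):
        wider = MotifDefinition(
            positions=[(n, s | {"G"}) for n, s in default_motif.positions],
            spacings=[(max(0, lo - 2), hi + 2) for lo, hi in default_motif.spacings],
            centers=default_motif.centers,
            companion=Companion(residues=frozenset("FYWG")),
            reference_positions=default_motif.reference_positions,
        )
        for _ in range(40):
            seq = "".join(rng.choice(LETTERS, size=140))
            if scan_linear(SequenceRecord("s", seq), default_motif).matched:
                assert scan_linear(SequenceRecord("s", seq), wider).matched


class TestScanAligned:
    def test_reference_matches_itself_with_zero_deviation(self, anchor, default_motif):
        aln = align_to_reference(anchor.reference_record, anchor)
        cmap = map_positions(aln, anchor)
        m = scan_aligned(cmap, default_motif)[anchor.reference_record.identifier]
        assert m.matched and m.variant == "YRWFD"
        assert m.positions_in_query == tuple(
            anchor.domain_index(p) for p in anchor.anchor_positions
        )
        assert all(d == 0 for d in m.spacing_deviation)

    def test_panel_variants_recovered_through_alignment(self, anchor, default_motif):
        for rec, want in zip(
            synthetic_receptor_panel(),
            ("YRWFN", "YKWYN", "YRWFD", "FRFYN", "YKWFN", "YHWFN"),
        ):
            cmap = map_positions(align_to_reference(rec, anchor), anchor)
            m = scan_aligned(cmap, default_motif)[rec.identifier]
            assert m.matched and m.variant == want, rec.identifier

    def test_forbidden_residue_at_p5_unmatches(self, anchor, default_motif):
        ref = anchor.reference_record
        k = anchor.domain_index(169)
        q = SequenceRecord("q", ref.residues[: k - 1] + "A" + ref.residues[k:])
        cmap = map_positions(align_to_reference(q, anchor), anchor)
        assert not scan_aligned(cmap, default_motif)["q"].matched

    def test_deleted_reference_position_reported(self, anchor, default_motif):
        aln = align_to_reference(anchor.reference_record, anchor)
        cmap = map_positions(aln, anchor)
        cmap.columns[169] = None  # emulate a trimmed-away anchor column
        m = scan_aligned(cmap, default_motif)[anchor.reference_record.identifier]
        assert not m.matched and m.reason == "reference position deleted"


class TestDeriveMotif:
    def test_recovers_planted_definition_from_cohort(self, anchor, default_motif):
        """Five of the ten contact columns are conserved; the motif falls out."""
        block = synthetic_cohort_alignment(seed=7)
        profile = conservation_profile(block)
        cmap = map_positions(block, anchor, positions=list(CONTACT_POSITIONS))
        derived = derive_motif(profile, CONTACT_POSITIONS, cmap, anchor)
        assert derived.reference_positions == list(default_motif.reference_positions)
        assert [frozenset(s) for _, s in derived.positions] == [
            s for _, s in default_motif.positions
        ]
        assert derived.spacings == default_motif.spacings
        assert derived.companion == default_motif.companion

    def test_no_conserved_contacts_errors(self, anchor):
        block = synthetic_cohort_alignment(background_mutation_rate=0.95, seed=1)
        profile = conservation_profile(block)
        nonmotif = [p for p in CONTACT_POSITIONS if p not in anchor.anchor_positions]
        cmap = map_positions(block, anchor, positions=nonmotif)
        with pytest.raises(ValueError, match="no motif derivable"):
            derive_motif(profile, nonmotif, cmap, anchor)


class TestVariantTable:
    def test_unmatched_get_dash(self, default_motif):
        seqs = {
            "a": plant("YRWFN", default_motif.centers),
            "b": plant("YKWFN", default_motif.centers),
            "c": plant("YHWFN", default_motif.centers),
            "d": "A" * 120,
        }
        matches = {
            sid: scan_linear(SequenceRecord(sid, s), default_motif) for sid, s in seqs.items()
        }
        table = variant_table(matches)
        assert len(table) == 4
        assert list(table[table.protein_id == "d"].variant) == ["-"]
        assert table.matched.sum() == 3

    def test_reference_and_first_receptor_variants(self, anchor, default_motif):
        recs = [anchor.reference_record, synthetic_receptor_panel()[0]]
        matches = {r.identifier: scan_linear(r, default_motif) for r in recs}
        table = variant_table(matches)
        assert list(table.variant) == ["YRWFD", "YRWFN"]

    def test_empty_input(self):
        assert len(variant_table({})) == 0
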