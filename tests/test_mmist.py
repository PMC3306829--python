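"""Interface-motif extraction, grouping, and group-matching prediction."""

import pytest
from hypothesis import given, settings, strategies as st

from interolink import (
    ContactRecord,
    InteractionTable,
    SequenceRecord,
    build_group_interaction_map,
    build_motif_groups,
    extract_motifs,
    match_protein_to_group,
    predict_mmist,
)
from interolink.mmist import Motif, MotifGroup

from tests._oracles import mmist_rule_brute, motif_segments_regex

SEQ20 = "ACDEFGHIKLMNPQRSTVWY"


def _record(contacts, length=20):
    return ContactRecord("c1", "A", "B", SEQ20[:length], "MKVLY", frozenset(contacts), frozenset())


class TestExtractMotifs:
    def test_contiguous_run_of_five(self):
        (motif,) = extract_motifs(_record({1, 2, 3, 4, 5}, 10), "A")
        assert (motif.start, motif.end, motif.sequence) == (1, 5, "ACDEF")

    def test_gap_of_two_bridged_into_one_motif(self):
        (motif,) = extract_motifs(_record({1, 2, 3, 6, 7, 8}), "A")
        assert (motif.start, motif.end) == (1, 8)
        assert motif.sequence == SEQ20[:8]

    def test_gap_of_three_splits_and_short_segment_dropped(self):
        motifs = extract_motifs(_record({1, 2, 3, 7, 8, 9, 10, 11}), "A")
        assert [(m.start, m.end) for m in motifs] == [(7, 11)]

    def test_empty_contacts_no_motifs(self):
        assert extract_motifs(_record(set()), "A") == []

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError):
            extract_motifs(_record({1, 2, 3, 4, 5}), "C")

    @given(mask_bits=st.lists(st.booleans(), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_regex_oracle_and_direct_rules(self, mask_bits):
        length = len(mask_bits)
        contacts = {i + 1 for i, bit in enumerate(mask_bits) if bit}
        seq = (SEQ20 * 3)[:length]
        record = ContactRecord("c", "A", "B", seq, "MKVLY", frozenset(contacts), frozenset())
        motifs = extract_motifs(record, "A")
        mask = "".join("1" if bit else "0" for bit in mask_bits)
        assert [(m.start, m.end) for m in motifs] == motif_segments_regex(mask)
        for m in motifs:
            assert len(m.sequence) >= 5
            assert mask[m.start - 1] == "1" and mask[m.end - 1] == "1"
            assert "000" not in mask[m.start - 1 : m.end]


class TestGroups:
    def _two_motif_record(self, complex_id="c1", protein="A"):
        # two segments: 1-5 and 11-16
        return ContactRecord(
            complex_id, protein, "B", SEQ20, "MKVLY",
            frozenset(range(1, 6)) | frozenset(range(11, 17)), frozenset(),
        )

    def test_single_motif_protein_gets_no_group(self):
        groups = build_motif_groups([_record({1, 2, 3, 4, 5}, 10)])
        assert groups == []

    def test_motifs_pooled_across_complexes(self):
        rec1 = ContactRecord("c1", "A", "B", SEQ20, "MKVLY", frozenset(range(1, 6)), frozenset())
        rec2 = ContactRecord("c2", "A", "C", SEQ20, "MKVLY", frozenset(range(11, 17)), frozenset())
        (group,) = build_motif_groups([rec1, rec2])
        assert group.protein_id == "A"
        assert {(m.start, m.end) for m in group.motifs} == {(1, 5), (11, 16)}

    def test_duplicate_extraction_stored_once(self):
        rec = self._two_motif_record()
        (group,) = build_motif_groups([rec, self._two_motif_record("c2")])
        assert len(group.motifs) == 2

    def test_group_invariant_enforced(self):
        motif = Motif("ACDEF", 1, 5, "A")
        with pytest.raises(ValueError):
            MotifGroup("A", frozenset({motif}))


class TestGroupMap:
    def _groups(self):
        m1 = Motif("ACDEF", 1, 5, "R1")
        m2 = Motif("GHIKL", 6, 10, "R1")
        m3 = Motif("MNPQR", 1, 5, "R2")
        m4 = Motif("STVWY", 6, 10, "R2")
        return [
            MotifGroup("R1", frozenset({m1, m2})),
            MotifGroup("R2", frozenset({m3, m4})),
        ]

    def test_pair_with_groups_both_sides(self):
        gmap = build_group_interaction_map(
            InteractionTable.from_pairs([("R1", "R2")]), self._groups()
        )
        assert len(gmap) == 1

    def test_partner_without_group_skipped(self):
        gmap = build_group_interaction_map(
            InteractionTable.from_pairs([("R1", "R3")]), self._groups()
        )
        assert len(gmap) == 0

    def test_self_interaction_excluded(self):
        table = InteractionTable()
        table.add("R1", "R1")
        gmap = build_group_interaction_map(table, self._groups())
        assert len(gmap) == 0


class TestMatching:
    def _group(self, sequences):
        motifs = frozenset(
            Motif(seq, 1 + 10 * i, 10 * i + len(seq), "R") for i, seq in enumerate(sequences)
        )
        return MotifGroup("R", motifs)

    def test_all_motifs_required(self):
        group = self._group(["ACDEF", "GHIKL"])
        assert match_protein_to_group(SequenceRecord("p", "ACDEFWWGHIKL"), group)
        assert not match_protein_to_group(SequenceRecord("p", "ACDEFWW"), group)

    def test_overlapping_matches_permitted(self):
        group = self._group(["ACDEF", "CDEFG"])
        assert match_protein_to_group(SequenceRecord("p", "ACDEFG"), group)

    def test_hamming_tolerance_option(self):
        group = self._group(["ACDEF", "GHIKL"])
        protein = SequenceRecord("p", "ACDEWGHIKL")  # one mismatch in ACDEF
        assert not match_protein_to_group(protein, group)
        assert match_protein_to_group(protein, group, max_mismatch=1)

    def test_x_never_matches(self):
        group = self._group(["ACDEF", "GHIKL"])
        assert not match_protein_to_group(SequenceRecord("p", "ACDXFWWGHIKL"), group, max_mismatch=1)


class TestPredict:
    def _map_and_targets(self):
        groups = [
            MotifGroup("R1", frozenset({Motif("ACDEF", 1, 5, "R1"), Motif("GHIKL", 11, 15, "R1")})),
            MotifGroup("R2", frozenset({Motif("MNPQR", 1, 5, "R2"), Motif("STVWY", 11, 15, "R2")})),
        ]
        gmap = build_group_interaction_map(InteractionTable.from_pairs([("R1", "R2")]), groups)
        targets = [
            SequenceRecord("T1", "ACDEFWWWGHIKL"),
            SequenceRecord("T2", "MNPQRWWWSTVWY"),
            SequenceRecord("T3", "PPPPPPPPPP"),
        ]
        return gmap, targets

    def test_single_matching_pair(self):
        gmap, targets = self._map_and_targets()
        assert predict_mmist(targets, gmap).edge_set() == {("T1", "T2")}

    def test_protein_matching_both_groups_never_self_paired(self):
        gmap, _ = self._map_and_targets()
        both = SequenceRecord("T1", "ACDEFGHIKLMNPQRSTVWY")
        assert predict_mmist([both], gmap).edge_set() == set()

    def test_map_entry_order_irrelevant(self):
        gmap, targets = self._map_and_targets()
        flipped = type(gmap)(entries=[(g2, g1) for g1, g2 in gmap.entries])
        assert predict_mmist(targets, gmap).edge_set() == predict_mmist(targets, flipped).edge_set()

    def test_matches_rule_enumeration_on_random_fixture(self, rng):
        from interolink.io_formats import RESIDUE_ORDER

        proteins = []
        for i in range(8):
            seq = "".join(rng.choice(list(RESIDUE_ORDER), size=30))
            proteins.append(SequenceRecord(f"P{i}", seq))
        # implant group motifs into a few proteins
        g1 = ("WWWWW", "HHHHH")
        g2 = ("YYYYY", "RRRRR")
        proteins[0] = SequenceRecord("P0", g1[0] + proteins[0].sequence[5:20] + g1[1])
        proteins[3] = SequenceRecord("P3", g2[0] + proteins[3].sequence[5:20] + g2[1])
        proteins[5] = SequenceRecord("P5", g1[0] + g1[1] + proteins[5].sequence[10:])
        groups = [
            MotifGroup("R1", frozenset({Motif(g1[0], 1, 5, "R1"), Motif(g1[1], 11, 15, "R1")})),
            MotifGroup("R2", frozenset({Motif(g2[0], 1, 5, "R2"), Motif(g2[1], 11, 15, "R2")})),
        ]
        gmap = build_group_interaction_map(InteractionTable.from_pairs([("R1", "R2")]), groups)
        expected = mmist_rule_brute(proteins, [(set(g1), set(g2))])
        assert predict_mmist(proteins, gmap).edge_set() == expected
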