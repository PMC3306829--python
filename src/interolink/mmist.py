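"""Motif-motif interaction prediction (M-MIST-style group matching).

Interface motifs are contiguous polypeptide segments of five residues or
longer built from residues in contact with a partner protein (<4 A side
chains, precomputed upstream); up to two consecutive non-contact residues
are bridged into a segment. All motifs of one protein, pooled over its
complexes, form its motif group when there are at least two of them.
Reference interactions between group-bearing proteins induce a group-group
interaction map; a target pair is predicted to interact when one protein
matches one group and the other protein matches the partner group.

"Matches" means every motif sequence of the group occurs as an exact
substring of the protein (an optional Hamming tolerance is available);
motifs may overlap in the target and their order is unconstrained. 'X'
residues never match.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ContactRecord, InteractionTable, SequenceRecord
from .network import InteractionNetwork

MIN_MOTIF_LENGTH = 5
MAX_GAP = 2  # non-contact residues bridged inside one segment
MIN_GROUP_SIZE = 2


@dataclass(frozen=True)
class Motif:
    """An interface segment (1-based inclusive coordinates on its source protein)."""

    sequence: str
    start: int
    end: int
    source_protein_id: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("motif coordinates inconsistent with sequence length")
        if len(self.sequence) < MIN_MOTIF_LENGTH:
            raise ValueError(f"motif shorter than {MIN_MOTIF_LENGTH} residues")


@dataclass(frozen=True)
class MotifGroup:
    """The set (>=2) of interface motifs of one protein."""

    protein_id: str
    motifs: frozenset[Motif]

    def __post_init__(self) -> None:
        if len(self.motifs) < MIN_GROUP_SIZE:
            raise ValueError(f"motif group needs >= {MIN_GROUP_SIZE} motifs")

    @property
    def motif_sequences(self) -> frozenset[str]:
        return frozenset(m.sequence for m in self.motifs)


@dataclass
class GroupInteractionMap:
    """Unordered pairs of motif groups derived from reference interactions."""

    entries: list[tuple[MotifGroup, MotifGroup]]

    def __len__(self) -> int:
        return len(self.entries)


def extract_motifs(record: ContactRecord, side: str) -> list[Motif]:
    """Interface motifs on one side of a complex.

    Contact residues separated by at most :data:`MAX_GAP` non-contact
    residues are merged into one segment (bridged residues included in the
    emitted sequence); segments spanning >= :data:`MIN_MOTIF_LENGTH`
    residues become motifs.
    """
    if side == "A":
        contacts, seq, protein_id = record.contacts_a, record.sequence_a, record.protein_a_id
    elif side == "B":
        contacts, seq, protein_id = record.contacts_b, record.sequence_b, record.protein_b_id
    else:
        raise ValueError(f"side must be 'A' or 'B', got {side!r}")
    if not contacts:
        return []
    positions = sorted(contacts)
    segments: list[tuple[int, int]] = []
    start = prev = positions[0]
    for pos in positions[1:]:
        if pos - prev - 1 <= MAX_GAP:
            prev = pos
        else:
            segments.append((start, prev))
            start = prev = pos
    segments.append((start, prev))
    return [
        Motif(seq[s - 1 : e], s, e, protein_id)
        for s, e in segments
        if e - s + 1 >= MIN_MOTIF_LENGTH
    ]


def build_motif_groups(records: list[ContactRecord]) -> list[MotifGroup]:
    """Pool motifs per protein across all its interfaces; keep groups of >=2."""
    pooled: dict[str, set[Motif]] = {}
    for record in records:
        for side in ("A", "B"):
            for motif in extract_motifs(record, side):
                pooled.setdefault(motif.source_protein_id, set()).add(motif)
    return [
        MotifGroup(protein_id, frozenset(motifs))
        for protein_id, motifs in sorted(pooled.items())
        if len(motifs) >= MIN_GROUP_SIZE
    ]


def build_group_interaction_map(
    reference_ppis: InteractionTable, groups: list[MotifGroup]
) -> GroupInteractionMap:
    """Lift reference interactions to pairs of motif groups."""
    by_protein = {g.protein_id: g for g in groups}
    entries = []
    seen: set[tuple[str, str]] = set()
    for r1, r2 in reference_ppis:
        if r1 == r2:
            continue
        g1, g2 = by_protein.get(r1), by_protein.get(r2)
        if g1 is None or g2 is None:
            continue
        key = (g1.protein_id, g2.protein_id)
        if key not in seen:
            seen.add(key)
            entries.append((g1, g2))
    return GroupInteractionMap(entries)


def match_protein_to_group(
    protein: SequenceRecord, group: MotifGroup, max_mismatch: int = 0
) -> bool:
    """True iff every motif sequence of the group occurs in the protein.

    With ``max_mismatch > 0`` a motif matches any window within that Hamming
    distance; windows containing 'X' never match.
    """
    seq = protein.sequence
    for motif_seq in group.motif_sequences:
        if max_mismatch == 0:
            if motif_seq not in seq or "X" in motif_seq:
                return False
            continue
        found = False
        for start in range(len(seq) - len(motif_seq) + 1):
            window = seq[start : start + len(motif_seq)]
            if "X" in window or "X" in motif_seq:
                continue
            mismatches = sum(a != b for a, b in zip(window, motif_seq))
            if mismatches <= max_mismatch:
                found = True
                break
        if not found:
            return False
    return True


def predict_mmist(
    target: list[SequenceRecord],
    group_map: GroupInteractionMap,
    max_mismatch: int = 0,
    label: str = "mmist",
) -> InteractionNetwork:
    """Predict target interactions from the group-interaction map.

    For every map entry (G1, G2) and distinct target proteins t1 matching G1
    and t2 matching G2 (either orientation), the edge (t1, t2) is predicted.
    """
    matches: dict[str, set[str]] = {}  # group protein_id -> matching target ids
    groups = {g.protein_id: g for pair in group_map.entries for g in pair}
    for gid, group in groups.items():
        matches[gid] = {
            p.id for p in target if match_protein_to_group(p, group, max_mismatch)
        }
    net = InteractionNetwork()
    for g1, g2 in group_map.entries:
        for t1 in matches[g1.protein_id]:
            for t2 in matches[g2.protein_id]:
                if t1 != t2:
                    net.add_edge(t1, t2, label)
    return net
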