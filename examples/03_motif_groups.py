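"""Extract interface motifs from contact records and match motif groups.

A contact record lists which residues of each protein touch the partner
(<4 A side chains, precomputed upstream). Runs of contact residues bridged
by at most two non-contact residues become motifs when they span >= 5
residues; a protein's motifs (>= 2 of them) form its motif group, and
reference interactions between group-bearing proteins let us predict new
pairs by exact substring matching.
"""

from interolink import (
    ContactRecord,
    InteractionTable,
    SequenceRecord,
    build_group_interaction_map,
    build_motif_groups,
    extract_motifs,
    predict_mmist,
)

seq_a = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
seq_b = "MNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
record = ContactRecord(
    "complex1", "REF_A", "REF_B", seq_a, seq_b,
    contacts_a=frozenset(range(1, 7)) | frozenset(range(15, 21)),   # two segments on A
    contacts_b=frozenset(range(3, 9)) | frozenset(range(21, 27)),   # two segments on B
)

for side in ("A", "B"):
    for motif in extract_motifs(record, side):
        print(f"side {side}: positions {motif.start}-{motif.end}  {motif.sequence}")

groups = build_motif_groups([record])
gmap = build_group_interaction_map(InteractionTable.from_pairs([("REF_A", "REF_B")]), groups)

target = [
    SequenceRecord("T1", "WW" + seq_a[0:6] + "HHH" + seq_a[14:20] + "WW"),  # matches A's group
    SequenceRecord("T2", "KK" + seq_b[2:8] + "GGG" + seq_b[20:26] + "KK"),  # matches B's group
    SequenceRecord("T3", "PPPPPPPPPPPPPPPPPPPP"),
]
network = predict_mmist(target, gmap)
print("predicted interactions:", network.edges)
# (T1, T2) is predicted because T1 carries every motif of REF_A's group and
# T2 every motif of REF_B's group, mirroring the reference interaction.
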