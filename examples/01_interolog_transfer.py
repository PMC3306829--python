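"""Transfer reference interactions onto a target proteome by homology.

Builds a tiny reference proteome with one known interaction, creates target
orthologs at 95% and 60% identity, and shows that only the high-identity
pair survives the 70%-identity / 90%-coverage filter.
"""

import numpy as np

from interolink import (
    InteractionTable,
    build_homolog_map,
    generate_proteome,
    local_align,
    mutate_to_identity,
    transfer_interactions,
)

rng = np.random.default_rng(0)
reference = generate_proteome(4, (100, 100), rng, prefix="REF")
ppis = InteractionTable.from_pairs(
    [(reference[0].id, reference[1].id), (reference[2].id, reference[3].id)]
)

# orthologs: the first pair conserved (95%), the second diverged (60%)
target = [
    mutate_to_identity(reference[0], 95, rng, new_id="PIG_A"),
    mutate_to_identity(reference[1], 95, rng, new_id="PIG_B"),
    mutate_to_identity(reference[2], 60, rng, new_id="PIG_C"),
    mutate_to_identity(reference[3], 60, rng, new_id="PIG_D"),
]

for t, r in zip(target, reference):
    hit = local_align(t, r)
    print(f"{t.id} vs {r.id}: identity {hit.identity_pct:5.1f}%  coverage {hit.query_coverage_pct:5.1f}%")

hmap = build_homolog_map(target, reference, identity_cutoff_pct=70, coverage_cutoff_pct=90)
network = transfer_interactions(hmap, ppis)
print("\ntransferred interactions:", network.edges)
# Only (PIG_A, PIG_B) is predicted: the diverged pair falls below the
# identity cutoff, so its reference interaction is not transferred.
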