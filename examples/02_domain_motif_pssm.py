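"""Predict an interaction between a domain carrier and a motif carrier.

Builds a PSSM from three aligned instances of a binding motif, scans a
proteome for matches, and applies the domain-vs-motif rule: protein X has
the domain (e-value <= 0.01), protein Y matches the domain's motif profile,
so (X, Y) is predicted.
"""

from interolink import DomainAnnotation, SequenceRecord, build_pssm, predict_dmist, scan_pssm

instances = ["ACDEF", "ACDEW", "ACDEY"]  # aligned motif instances
pssm = build_pssm(instances, motif_id="M1", domain_id="SH3")
print("column probabilities at position 5 (F/W/Y split):")
print("  F:", round(pssm.scores[4][4], 3), " W:", round(pssm.scores[4][18], 3),
      " Y:", round(pssm.scores[4][19], 3))

proteome = [
    SequenceRecord("X", "MKVLYWWWWWMKVLY"),        # carries the SH3 domain
    SequenceRecord("Y", "GGGGGACDEFGGGGG"),        # contains the motif
    SequenceRecord("Z", "PPPPPPPPPPPPPPP"),        # neither
]
annotations = [DomainAnnotation("X", "SH3", 1e-6)]

hits = scan_pssm(pssm, proteome[1], threshold=0.8)
print("scan hits on Y:", [(h.start, round(h.normalized_score, 3)) for h in hits])

network = predict_dmist(proteome, annotations, [pssm], e_cutoff=0.01, scan_threshold=0.8)
print("predicted interactions:", network.edges)
# The single edge (X, Y) pairs the domain carrier with the motif carrier;
# Z matches nothing and no self-pairs are produced.
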