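# Methods

This note records the models, conventions, numerical choices and known
limitations of the package, in the order the pipeline applies them.

## Sequence model and coordinates

Proteins are uppercase strings over the 20 standard amino acids plus `X`
(unknown). `X` is treated conservatively everywhere it matters: it never
matches in exact-substring motif matching, it scores the column minimum in
PSSM scans, and it scores as a mismatch (even against itself) under simple
match/mismatch alignment scoring. All residue and contact coordinates
surfaced to users are 1-based inclusive, the convention of sequence-feature
annotation.

## Local alignment and the interolog transfer

Homology is assessed by optimal Smith–Waterman local alignment. Default
scoring is BLOSUM62 with affine gaps, open 11 / extend 1 (a gap of length L
costs 11 + (L−1)·1), the classic protein-BLAST parameterisation;
match/mismatch scoring is available for didactic and oracle use. Two
derived quantities drive filtering:

* **percent identity** = identities / alignment columns × 100, gap columns
  included in the denominator;
* **query coverage** = aligned query span / query length × 100, taken over
  the *target* protein (the query of the search).

Optimal local alignments are frequently non-unique. Rather than reporting
an arbitrary traceback, the aligner deterministically selects, among all
co-optimal alignments, the one with the most aligned columns, breaking
remaining ties by most identities, then most query residues aligned. This
is resolved exactly inside the dynamic programme: each cell holds the tuple
(score, columns, identities, query-consumed) encoded in a single int64 in
mixed radix (base 4096), so tuple addition and maximisation are single
integer operations and lexicographic optimality composes across DP cells.
The encoding requires integral substitution and gap scores (all standard
matrices are integral) and sequences shorter than 4096 residues. The kernel
is JIT-compiled with numba when available, with an identical pure-Python
fallback. Alignments with non-positive optimal score report identity 0 and
coverage 0.

Interolog transfer maps every reference interaction through the homolog
map: "ortholog" is implemented as *any* above-threshold homolog, not
reciprocal-best-hit, because the filtering protocol is defined purely by
identity and coverage thresholds; a `reciprocal_best` switch restricts to
mutual best hits. Multiple reference species are handled by running the
transfer per reference set with a provenance label and unioning the
results. Self-pairs are never emitted. Default thresholds: identity 70%,
coverage 90%; the cutoff sweep (36–100%) reuses one all-vs-all alignment
pass, which also guarantees the threshold-monotonicity property
structurally.

## PSSMs and domain–motif prediction

`build_pssm` turns aligned, equal-length, gap-free motif instances into
per-position residue probabilities (q+p)/(N+B). The pseudocount scheme is
not dictated by the count formula itself; the default is a flat p = 0.05
per residue (B = 1), configurable to any non-negative L×20 array with
constant column mass. Columns sum to exactly 1 by construction.

Scanning slides the profile along a sequence and scores each window as the
sum of log probabilities, min–max normalised:

    normalized = (window − Σ min column) / (Σ max column − Σ min column)

so profiles of different lengths share one [0, 1] threshold scale. The
default scan threshold is 0.8; a threshold of 1.0 accepts only windows that
attain the profile's maximum at every position (for a single-instance
profile, exactly the consensus sequence — the mode used by the
planted-truth tests). A degenerate profile whose best and worst windows
coincide normalises to 1.0 everywhere. Matrices loaded from a library file
may hold arbitrary scores; scanning applies the log transform only when
every entry is positive, otherwise the raw scores are summed under the same
normalisation. A 1e-12 slack on the threshold comparison absorbs float
rounding at the boundary.

Prediction pairs every protein carrying domain D at e-value ≤ 0.01 (the
same cutoff used for the validation annotations) with every protein hitting
any profile of D; multiple qualifying (domain, profile) routes collapse to
one undirected edge, and self-pairs are removed. The upstream exclusion of
domains by their number of putative interactors is not reimplemented — its
direction is ambiguous in the source protocol, and profile libraries are a
pluggable input here, so the filter belongs to the library producer.

## Interface motifs and motif-group prediction

Contact records carry, per binary complex, the 1-based indices of residues
in contact with the partner (< 4 Å side chains, computed upstream of this
package). Sorted contact indices are merged into maximal segments wherever
consecutive contacts are separated by at most two non-contact residues;
bridged residues are part of the segment, which is emitted as a motif when
its total span is ≥ 5 residues. Motifs are pooled per protein over all its
complexes (set semantics: identical (sequence, start, end) stored once);
proteins with ≥ 2 motifs form motif groups. Reference interactions between
two group-bearing proteins populate the group-interaction map
(self-interactions excluded).

"Protein matches group" means every motif sequence of the group occurs as
an exact, case-sensitive substring; motifs may overlap in the target and
their order and spacing are unconstrained. Exact matching is the most
defensible reading of an otherwise underspecified matching step and gives
an unambiguous test surface; a Hamming-distance tolerance (`max_mismatch`)
is available but defaults to 0. Duplicate motif sequences count once for
matching. Prediction enumerates map entries × matching target pairs in both
orientations, deduplicated, self-pairs excluded.

## Topology metrics

The merged network is the edge/node union with per-edge support = the set
of contributing method labels (support count 1–3 doubles as the package's
confidence score — a repository definition). Metrics follow the
Cytoscape-style conventions used in interactome analyses:

* betweenness is computed within each connected component, normalized by
  (N−1)(N−2)/2 with N the component size;
* closeness is the reciprocal mean shortest-path length within the
  component; isolated nodes score 0;
* clustering is 2e_n/(k_n(k_n−1)), 0 for degree < 2, and the network
  average is the mean over *all* nodes (the convention of the common
  network-analysis tooling; averaging only over k ≥ 2 nodes is the main
  alternative and is easy to compute from the per-node values);
* the topological coefficient averages J(n,m) (shared neighbours of n and
  m, +1 if n–m is an edge) over all m sharing at least one neighbour with
  n, divided by k_n; nodes with no such m (or degree 0) score 0;
* diameter is the largest finite eccentricity, the radius the minimum
  eccentricity over the largest component, characteristic path length the
  mean over connected pairs, and the connected-pair fraction the share of
  all unordered node pairs that are connected (reported as a percentage in
  the run report). A network radius of 1, as sometimes reported for large
  interactomes, requires a dominating node under this definition; the
  package computes the standard quantity rather than imitating such
  values.

**Power-law fit.** P(k) is fitted on raw, un-binned log–log points
(zero-count and zero degrees excluded — their logarithm is undefined) by
least squares *weighted by n_k*, so each node rather than each distinct
degree counts once. The unweighted regression is severely flattened by the
sporadic single-node counts that populate the tail of any finite sample
(on 5,000-node configuration-model graphs with γ = 2.2 it returns
γ̂ ≈ 1.2–1.4), an artefact of giving a one-node bin the same leverage as a
three-thousand-node bin; per-node weighting recovers γ̂ ≈ 2.05–2.1 on the
same graphs while leaving exact power-law histograms fitted to machine
precision with R² = 1. R² is the weighted coefficient of determination,
defined as 1 when the input is exactly collinear (including the
zero-variance case of a uniform distribution).

## Randomization and gold-standard validation

Null networks draw the observed number of unordered protein pairs uniformly
with replacement from the proteome (self-pairs redrawn, duplicates allowed,
matching sampling-with-replacement semantics and the no-self-loop property
of the predicted networks). The empirical p-value is the plain exceedance
fraction #(null ≥ observed)/reps, reported to three decimals so a
never-exceeded observation prints "0.000"; the add-one (Davison–Hinkley)
estimator, which cannot return 0, is available by flag. The protocol-scale
repetition counts are 100 (domain-pair support) and 10,000 (GO sharing);
both are configurable, and the test suite and acceptance script run 15–100
repetitions, which exercises the identical code path at desk scale.

GO sharing is the fraction of edges whose endpoints share ≥ 1 GO identifier
in any of the three ontologies. Annotations are compared as given — no
ontology-graph propagation and no filtering of uninformative terms — and
edges with an unannotated endpoint stay in the denominator (conservative;
switchable). The empty network has no defined sharing fraction and raises.

Gold-standard evaluation counts TP/FN over the positive set and FP/TN over
the negative set (the sets must be disjoint); accuracy is
(TP+TN)/(TP+TN+FP+FN) and precision the mean of the PPI precision
TP/(TP+FP) and non-PPI precision TN/(TN+FN). An undefined component (empty
denominator, e.g. under an all-positive predictor) is excluded from the
mean and flagged rather than silently treated as 0. A GSN generator draws
uniform random pairs excluding the GSP and any further excluded set.

## Synthetic fixtures

The generator exists so that every planted signal is *exactly* recoverable:

* sequences are i.i.d. uniform over the 20 residues, lengths 90–130
  (planted-signal carriers fixed at 100 so identity arithmetic is exact);
* interolog plants are substitution-only mutants (no indels) at 95/92/88%
  identity — comfortably above the 70% cutoff yet spread out so cutoff
  sweeps show structure — with decoys at 45%, which fail on identity and,
  when the local alignment retreats to a conserved core, on coverage;
* domain–motif plants implant a unique 8-mer consensus into one carrier and
  annotate a second protein with the matching domain at e = 1e-5, plus
  decoy annotations (weak e-value 0.5; a domain with no profile);
* motif-group plants build reference complexes with two 6-residue interface
  segments per side (segment gap ≫ 2 so extraction yields two motifs) and
  implant both motifs of each group into one target carrier;
* every implanted k-mer is drawn to be absent from all sequences built so
  far and audited after assembly to occur in exactly one target protein;
  the ~1e-4-probability audit failure triggers a deterministic rebuild with
  a derived seed;
* GO terms are shared across planted edges with probability 0.7, domain
  pairs from a small iPfam-style pool support them with probability 0.8,
  and every protein gets a private background term;
* the gold-standard positive set is the planted edges plus three
  deliberately unrecoverable background pairs (so FN > 0 and accuracy < 1);
  the negative set is drawn disjoint from all planted edges (so FP = 0 in
  the bundle's contract).

Scale-free graphs sample degrees from P(k) ∝ k^−γ on k ∈ [1, n−1] and
realise them by configuration-model pairing with self-loops removed and
multi-edges collapsed, which perturbs only the extreme tail.

What the fixtures deliberately do **not** model: realistic amino-acid
composition, homologous gene families (paralogy confusing the homolog map),
indel evolution, correlated domain architectures, GO-term hierarchy, or
database-scale input sizes. Passing the planted-truth tests therefore
demonstrates algorithmic correctness of the three rules and the
surrounding machinery — not predictive performance on real proteomes,
which depends entirely on the quality and coverage of the reference
interactomes, profile libraries and contact records supplied.

## Determinism and problem sizes

All randomness flows through `numpy.random.default_rng` seeded from
user-supplied integers; derived seeds stay below 2^31. Reports contain no
wall-clock data and all collections are emitted in sorted order, so
identical configurations reproduce byte-identical outputs. The test suite
and acceptance script run at desk scale by design: proteomes of tens of
proteins with sequences of ~100 residues, 200-graph oracle sweeps capped at
40 nodes, a 5,000-node graph for fit recovery, and 100-repetition nulls —
sizes chosen so the full battery completes in well under a minute while
exercising every code path the protocol-scale runs would use.
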