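"""Synthetic input generation with planted, exactly recoverable ground truth.

Every input class the pipeline consumes can be generated here: proteomes,
reference interactions, PSSM libraries with domain annotations, interface
contact records, GO tables, domain-pair catalogues, and gold-standard sets.
The central contract is that :func:`plant_interaction_scenario` builds a
bundle whose expected edge sets are recovered *exactly* by the three
prediction methods at their default thresholds:

* interolog plants are substitution-only mutants with analytically
  controlled global identity (no indels), so the aligner recovers the
  planted identity to within one position's granularity;
* domain-motif and motif-group plants use implanted k-mers verified to be
  unique across the target proteome, so exact/consensus matching cannot
  produce off-target edges.

Sequences are i.i.d. uniform over the 20 standard residues — real proteome
composition bias, homologous families, and indel evolution are deliberately
absent (see the methods note for what this does and does not exercise).
All randomness flows through one ``numpy`` generator seeded from the spec.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dmist import PSSM, build_pssm
from .io_formats import (
    ContactRecord,
    DomainAnnotation,
    DomainPairSet,
    GOAnnotation,
    GO_CATEGORIES,
    InteractionTable,
    RESIDUE_ORDER,
    SequenceRecord,
    write_contact_records,
    write_domain_annotations,
    write_domain_pairs,
    write_fasta,
    write_go_annotations,
    write_interaction_table,
)
from .network import Edge, InteractionNetwork, canonical_pair
from .validation import generate_gsn

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "generate_proteome",
    "mutate_to_identity",
    "plant_interaction_scenario",
    "generate_scale_free_graph",
    "write_bundle",
]


def _as_rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUE_ORDER), size=length))


def generate_proteome(
    n: int,
    length_range: tuple[int, int] = (90, 130),
    seed: int | np.random.Generator = 0,
    prefix: str = "P",
) -> list[SequenceRecord]:
    """``n`` random proteins with i.i.d. uniform residues; deterministic per seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(seed)
    low, high = length_range
    records = []
    for i in range(n):
        length = int(rng.integers(low, high + 1))
        records.append(SequenceRecord(f"{prefix}{i + 1:04d}", _random_sequence(rng, length)))
    return records


def mutate_to_identity(
    record: SequenceRecord,
    target_identity_pct: float,
    seed: int | np.random.Generator = 0,
    new_id: str | None = None,
) -> SequenceRecord:
    """Substitute exactly round((1 - t/100) L) positions with different residues.

    No indels are introduced, so the global identity of the mutant equals the
    target within one position's granularity and a full-span local alignment
    recovers it.
    """
    if not 0 < target_identity_pct <= 100:
        raise ValueError("target identity must lie in (0, 100]")
    rng = _as_rng(seed)
    length = len(record.sequence)
    n_sub = round((1 - target_identity_pct / 100.0) * length)
    positions = rng.choice(length, size=n_sub, replace=False) if n_sub else []
    seq = list(record.sequence)
    for pos in positions:
        alternatives = [aa for aa in RESIDUE_ORDER if aa != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return SequenceRecord(
        new_id or f"{record.id}_m{target_identity_pct:g}", "".join(seq)
    )


def generate_scale_free_graph(
    n: int, gamma: float, seed: int | np.random.Generator = 0
) -> InteractionNetwork:
    """A configuration-model graph with degrees drawn from P(k) ~ k^-gamma.

    Degrees are sampled on k in [1, n-1]; the pairing is simplified by
    rejecting self-loops and collapsing multi-edges, which perturbs the
    realised degree sequence only in the extreme tail.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if gamma <= 1:
        raise ValueError("gamma must be > 1")
    rng = _as_rng(seed)
    ks = np.arange(1, n)
    weights = ks.astype(float) ** -gamma
    weights /= weights.sum()
    degrees = rng.choice(ks, size=n, p=weights)
    if degrees.sum() % 2:
        degrees[0] += 1
    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    net = InteractionNetwork()
    for node in g.nodes:
        net.add_node(f"N{node:05d}")
    for a, b in g.edges:
        net.add_edge(f"N{a:05d}", f"N{b:05d}", "synthetic")
    return net


# ---------------------------------------------------------------------------
# planted interaction scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted scenario; the seed fully determines the bundle."""

    seed: int = 0
    n_background_target: int = 10
    n_background_reference: int = 5
    length_range: tuple[int, int] = (90, 130)
    planted_length: int = 100  # carriers of planted signal (identity arithmetic exact)
    interolog_identities: tuple[float, ...] = (95.0, 92.0, 88.0)
    interolog_decoy_identity: float = 45.0
    n_interolog_decoys: int = 2
    n_dmist_plants: int = 2
    dmist_motif_length: int = 8
    n_mmist_plants: int = 2
    mmist_motif_length: int = 6
    go_sharing_prob: float = 0.7
    ipfam_support_prob: float = 0.8
    n_gsp_extra: int = 3
    n_gsn: int = 20


@dataclass
class FixtureBundle:
    """A complete, self-consistent input bundle plus its ground truth."""

    spec: FixtureSpec
    target: list[SequenceRecord]
    reference: list[SequenceRecord]
    reference_ppis: InteractionTable
    pssm_library: list[PSSM]
    domain_annotations: list[DomainAnnotation]
    contact_records: list[ContactRecord]
    go_annotations: list[GOAnnotation]
    domain_pairs: DomainPairSet
    gsp: InteractionTable
    gsn: InteractionTable
    expected: dict[str, set[Edge]] = field(default_factory=dict)

    @property
    def target_ids(self) -> list[str]:
        return [r.id for r in self.target]


def _unique_kmer(rng: np.random.Generator, k: int, haystacks: list[str], reserved: set[str]) -> str:
    for _ in range(1000):
        kmer = _random_sequence(rng, k)
        if kmer in reserved:
            continue
        if any(kmer in text for text in haystacks):
            continue
        return kmer
    raise RuntimeError("could not draw a unique k-mer")


def _implant(seq: str, kmer: str, start0: int) -> str:
    return seq[:start0] + kmer + seq[start0 + len(kmer) :]


def plant_interaction_scenario(spec: FixtureSpec) -> FixtureBundle:
    """Build a bundle whose planted edges the three methods recover exactly.

    Construction is retried with a derived seed in the (rare) event that a
    random background sequence collides with an implanted k-mer; the final
    bundle always passes its own uniqueness audit.
    """
    last_error: Exception | None = None
    for attempt in range(5):
        try:
            return _build_scenario(spec, spec.seed + attempt * 1000003)
        except _UniquenessViolation as exc:  # pragma: no cover - ~1e-4 likelihood
            last_error = exc
    raise RuntimeError(f"fixture construction failed repeatedly: {last_error}")


class _UniquenessViolation(RuntimeError):
    pass


def _build_scenario(spec: FixtureSpec, seed: int) -> FixtureBundle:
    rng = np.random.default_rng(seed)
    L = spec.planted_length
    if spec.mmist_motif_length < 5:
        raise ValueError("motif groups need motifs of >= 5 residues")
    if 2 * spec.dmist_motif_length + 10 > L or 2 * spec.mmist_motif_length + 10 > L:
        raise ValueError("planted motifs do not fit their carriers")

    target: list[SequenceRecord] = []
    reference: list[SequenceRecord] = []
    reference_ppis = InteractionTable()
    expected: dict[str, set[Edge]] = {"interolog": set(), "dmist": set(), "mmist": set()}

    # background proteins (never endpoints of any planted prediction)
    target += generate_proteome(spec.n_background_target, spec.length_range, rng, prefix="TBG")
    reference += generate_proteome(
        spec.n_background_reference, spec.length_range, rng, prefix="RBG"
    )

    # --- interolog plants: reference pair + high-identity target orthologs
    for i, identity in enumerate(spec.interolog_identities):
        ra = SequenceRecord(f"RIA{i:02d}", _random_sequence(rng, L))
        rb = SequenceRecord(f"RIB{i:02d}", _random_sequence(rng, L))
        reference += [ra, rb]
        reference_ppis.add(ra.id, rb.id, "reference")
        ta = mutate_to_identity(ra, identity, rng, new_id=f"TIA{i:02d}")
        tb = mutate_to_identity(rb, identity, rng, new_id=f"TIB{i:02d}")
        target += [ta, tb]
        if identity >= 70.0:
            expected["interolog"].add(canonical_pair(ta.id, tb.id))
    # decoys: reference pair whose only target homolog sits far below the cutoff
    for i in range(spec.n_interolog_decoys):
        rc = SequenceRecord(f"RID{i:02d}", _random_sequence(rng, L))
        rd = SequenceRecord(f"RIE{i:02d}", _random_sequence(rng, L))
        reference += [rc, rd]
        reference_ppis.add(rc.id, rd.id, "reference")
        target.append(mutate_to_identity(rc, spec.interolog_decoy_identity, rng, new_id=f"TID{i:02d}"))

    # --- domain-motif plants: X carries the domain, Y carries the profile consensus
    pssm_library: list[PSSM] = []
    domain_annotations: list[DomainAnnotation] = []
    special_kmers: dict[str, str] = {}  # kmer -> sole target carrier id

    def _haystacks() -> list[str]:
        return [r.sequence for r in target + reference]

    for j in range(spec.n_dmist_plants):
        domain_id = f"DOM{j:03d}"
        motif = _unique_kmer(rng, spec.dmist_motif_length, _haystacks(), set(special_kmers))
        x = SequenceRecord(f"TDX{j:02d}", _random_sequence(rng, L))
        y_seq = _random_sequence(rng, L)
        start0 = int(rng.integers(0, L - spec.dmist_motif_length + 1))
        y = SequenceRecord(f"TDY{j:02d}", _implant(y_seq, motif, start0))
        target += [x, y]
        special_kmers[motif] = y.id
        domain_annotations.append(DomainAnnotation(x.id, domain_id, 1e-5))
        pssm_library.append(build_pssm([motif], motif_id=f"MOT{j:03d}", domain_id=domain_id))
        expected["dmist"].add(canonical_pair(x.id, y.id))
    if spec.n_dmist_plants:
        # annotation decoys: weak e-value, and a domain with no profile
        weak = SequenceRecord("TDWEAK", _random_sequence(rng, L))
        orphan = SequenceRecord("TDORPH", _random_sequence(rng, L))
        target += [weak, orphan]
        domain_annotations.append(DomainAnnotation(weak.id, "DOM000", 0.5))
        domain_annotations.append(DomainAnnotation(orphan.id, "DOMNOPSSM", 1e-6))

    # --- motif-group plants: reference complex with two interface motifs a side
    contact_records: list[ContactRecord] = []
    mlen = spec.mmist_motif_length
    for j in range(spec.n_mmist_plants):
        motifs: dict[str, list[str]] = {}
        ref_seqs: dict[str, str] = {}
        for side_tag in ("A", "B"):
            kmers = []
            for _ in range(2):
                kmer = _unique_kmer(rng, mlen, _haystacks(), set(special_kmers) | set(kmers))
                kmers.append(kmer)
            seq = _random_sequence(rng, L)
            # two well-separated interface segments (gap >> 2 keeps them distinct motifs)
            s1 = 10  # 1-based start of first segment
            s2 = 10 + mlen + 20
            seq = _implant(seq, kmers[0], s1 - 1)
            seq = _implant(seq, kmers[1], s2 - 1)
            motifs[side_tag] = kmers
            ref_seqs[side_tag] = seq
        ra_id, rb_id = f"RMA{j:02d}", f"RMB{j:02d}"
        mask = frozenset(
            list(range(10, 10 + mlen)) + list(range(10 + mlen + 20, 10 + 2 * mlen + 20))
        )
        reference += [
            SequenceRecord(ra_id, ref_seqs["A"]),
            SequenceRecord(rb_id, ref_seqs["B"]),
        ]
        contact_records.append(
            ContactRecord(f"CPLX{j:02d}", ra_id, rb_id, ref_seqs["A"], ref_seqs["B"], mask, mask)
        )
        reference_ppis.add(ra_id, rb_id, "reference")
        carriers = {}
        for side_tag, tid in (("A", f"TMA{j:02d}"), ("B", f"TMB{j:02d}")):
            seq = _random_sequence(rng, L)
            seq = _implant(seq, motifs[side_tag][0], 4)
            seq = _implant(seq, motifs[side_tag][1], 4 + mlen + 10)
            rec = SequenceRecord(tid, seq)
            target.append(rec)
            carriers[side_tag] = rec
            for kmer in motifs[side_tag]:
                special_kmers[kmer] = tid
        expected["mmist"].add(canonical_pair(carriers["A"].id, carriers["B"].id))

    # uniqueness audit: every implanted k-mer occurs in exactly its one carrier
    for kmer, carrier in special_kmers.items():
        occurrences = [r.id for r in target if kmer in r.sequence]
        if occurrences != [carrier]:
            raise _UniquenessViolation(f"k-mer {kmer} found in {occurrences}, expected [{carrier}]")

    expected["merged"] = expected["interolog"] | expected["dmist"] | expected["mmist"]

    # --- validation inputs keyed to the expected merged edges
    ipfam_pool = [(f"IPA{i}", f"IPB{i}") for i in range(3)]
    domain_pairs = DomainPairSet(ipfam_pool)
    go_annotations: list[GOAnnotation] = []
    go_counter = 0
    for idx, (u, v) in enumerate(sorted(expected["merged"])):
        if rng.random() < spec.ipfam_support_prob:
            da, db = ipfam_pool[idx % len(ipfam_pool)]
            domain_annotations.append(DomainAnnotation(u, da, 1e-4))
            domain_annotations.append(DomainAnnotation(v, db, 1e-4))
        if rng.random() < spec.go_sharing_prob:
            go_counter += 1
            term = f"GO:{go_counter:07d}"
            category = GO_CATEGORIES[go_counter % len(GO_CATEGORIES)]
            go_annotations.append(GOAnnotation(u, term, category))
            go_annotations.append(GOAnnotation(v, term, category))
    for i, rec in enumerate(target):
        go_annotations.append(
            GOAnnotation(rec.id, f"GO:9{i:06d}", GO_CATEGORIES[i % len(GO_CATEGORIES)])
        )

    # --- gold standard: all expected edges plus unrecoverable extra positives
    gsp = InteractionTable.from_pairs(sorted(expected["merged"]), source="planted")
    background_ids = [r.id for r in target if r.id.startswith("TBG")]
    extra = 0
    while extra < spec.n_gsp_extra and len(background_ids) >= 2:
        i, j = rng.integers(0, len(background_ids), size=2)
        if i == j:
            continue
        pair = canonical_pair(background_ids[int(i)], background_ids[int(j)])
        if pair in gsp:
            continue
        gsp.add(*pair, source="unrecoverable")
        extra += 1
    gsn = generate_gsn(
        [r.id for r in target],
        spec.n_gsn,
        gsp,
        seed=int(rng.integers(2**31)),
        exclude=sorted(expected["merged"]),
    )

    return FixtureBundle(
        spec=spec,
        target=target,
        reference=reference,
        reference_ppis=reference_ppis,
        pssm_library=pssm_library,
        domain_annotations=domain_annotations,
        contact_records=contact_records,
        go_annotations=go_annotations,
        domain_pairs=domain_pairs,
        gsp=gsp,
        gsn=gsn,
        expected=expected,
    )


def write_bundle(bundle: FixtureBundle, outdir: str | os.PathLike) -> dict[str, str]:
    """Write every bundle component as plain text plus a ground-truth manifest."""
    from .dmist import write_pssm_library

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "target": "target.fasta",
        "reference": "reference.fasta",
        "reference_ppis": "reference_ppis.tsv",
        "pssm_library": "library.pssm",
        "domain_annotations": "domains.tsv",
        "contact_records": "contacts.tsv",
        "go_annotations": "go.tsv",
        "domain_pairs": "ipfam.tsv",
        "gsp": "gsp.tsv",
        "gsn": "gsn.tsv",
        "manifest": "manifest.json",
    }
    paths = {key: os.path.join(outdir, name) for key, name in paths.items()}
    write_fasta(bundle.target, paths["target"])
    write_fasta(bundle.reference, paths["reference"])
    write_interaction_table(bundle.reference_ppis, paths["reference_ppis"])
    write_pssm_library(bundle.pssm_library, paths["pssm_library"])
    write_domain_annotations(bundle.domain_annotations, paths["domain_annotations"])
    write_contact_records(bundle.contact_records, paths["contact_records"])
    write_go_annotations(bundle.go_annotations, paths["go_annotations"])
    write_domain_pairs(bundle.domain_pairs, paths["domain_pairs"])
    write_interaction_table(bundle.gsp, paths["gsp"])
    write_interaction_table(bundle.gsn, paths["gsn"])
    manifest = {
        "seed": bundle.spec.seed,
        "expected_edges": {
            method: sorted([list(edge) for edge in edges])
            for method, edges in bundle.expected.items()
        },
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
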