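"""Interolog transfer: map reference interactions onto a target proteome.

A reference interaction (R1, R2) is transferred to a target pair (t1, t2)
when t1 and t2 are homologs of R1 and R2 under a percent-identity cutoff
(the study sweeps 36-100% and settles on 70%) and a query-coverage cutoff
(>90% of the target protein aligned). Homology is assessed by optimal local
(Smith-Waterman) alignment; by default a BLOSUM62 substitution matrix with
affine gaps (open 11, extend 1 — a gap of length L costs open + (L-1) *
extend), the classic protein-BLAST parameterisation.

Percent identity is identities / alignment columns (gap columns included);
coverage is the aligned query span / query length, both x100. Optimal local
alignments are frequently non-unique; among co-optimal alignments this
module deterministically reports the one with the most aligned columns,
then the most identities, so identity reflects the longest optimal local
alignment rather than an arbitrary traceback. That tie-break is resolved
exactly inside the dynamic programme by maximising the tuple
(score, columns, identities, query-residues-aligned) encoded in one
integer per cell, which is why substitution and gap scores are required to
be integral (all standard matrices are).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .io_formats import InteractionTable, RESIDUE_ORDER, SequenceRecord
from .network import InteractionNetwork

_ALPHABET = RESIDUE_ORDER + "X"
_CHAR_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}

# mixed-radix encoding of (score, columns, identities, query-consumed):
# columns/identities/qcons each fit in [0, _RADIX); score carries the sign.
_RADIX = 4096


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution/gap parameters for local alignment.

    ``matrix`` names a Biopython substitution matrix (e.g. ``"BLOSUM62"``);
    set it to ``None`` for simple ``match``/``mismatch`` scoring. Gap
    penalties are positive integral costs: a gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.
    """

    matrix: str | None = "BLOSUM62"
    match: int = 1
    mismatch: int = -1
    gap_open: int = 11
    gap_extend: int = 1


#: Simple unit scoring (match +1 / mismatch -1 / -2 per gap column), used by
#: the small worked examples and the exhaustive test oracles.
UNIT_SCORING = AlignmentScoring(matrix=None, match=1, mismatch=-1, gap_open=2, gap_extend=2)


@dataclass(frozen=True)
class AlignmentHit:
    """One query-vs-subject local alignment summary."""

    query_id: str
    subject_id: str
    identity_pct: float
    query_coverage_pct: float
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.identity_pct <= 100 or not 0 <= self.query_coverage_pct <= 100:
            raise ValueError("identity/coverage outside [0, 100]")


@dataclass
class HomologMap:
    """reference protein id -> {target protein id: AlignmentHit}."""

    identity_cutoff_pct: float
    coverage_cutoff_pct: float
    mapping: dict[str, dict[str, AlignmentHit]] = field(default_factory=dict)

    def targets_of(self, reference_id: str) -> set[str]:
        return set(self.mapping.get(reference_id, ()))

    def add(self, reference_id: str, hit: AlignmentHit) -> None:
        self.mapping.setdefault(reference_id, {})[hit.query_id] = hit


@lru_cache(maxsize=8)
def _substitution_array(scoring: AlignmentScoring) -> np.ndarray:
    """21 x 21 integer substitution scores over the package alphabet."""
    size = len(_ALPHABET)
    if scoring.matrix is None:
        arr = np.full((size, size), int(scoring.mismatch), dtype=np.int64)
        np.fill_diagonal(arr, int(scoring.match))
        # 'X' is an unknown residue: scored as a mismatch even against itself
        arr[size - 1, size - 1] = int(scoring.mismatch)
        return arr
    matrix = substitution_matrices.load(scoring.matrix)
    arr = np.zeros((size, size), dtype=np.int64)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            value = matrix[a, b]
            if value != int(value):
                raise ValueError(f"substitution matrix {scoring.matrix} is not integral")
            arr[i, j] = int(value)
    return arr


def _sw_kernel(qarr, sarr, submat, gap_open, gap_extend, radix):
    """Local-alignment DP maximising (score, columns, identities, q-consumed).

    Three affine states per cell — M (residue vs residue), X (gap column in
    the query) and Y (gap column in the subject) — each holding the tuple
    encoded in one int64 (mixed radix, so addition of per-column
    contributions preserves lexicographic order). Alignments start and end
    in M: with positive gap penalties a flanking gap can always be trimmed
    at a strict gain. Returns the best encoded value; <= 0 means no
    positive-scoring local alignment exists.
    """
    n = qarr.shape[0]
    m = sarr.shape[0]
    r3 = radix * radix * radix
    r2 = radix * radix
    open_x = -gap_open * r3 + r2  # gap column in query: consumes subject only
    ext_x = -gap_extend * r3 + r2
    open_y = open_x + 1  # gap column in subject: consumes one query residue
    ext_y = ext_x + 1
    neg = -(np.int64(1) << np.int64(60))
    prev_m = np.full(m + 1, neg, dtype=np.int64)
    prev_x = np.full(m + 1, neg, dtype=np.int64)
    prev_y = np.full(m + 1, neg, dtype=np.int64)
    cur_m = np.full(m + 1, neg, dtype=np.int64)
    cur_x = np.full(m + 1, neg, dtype=np.int64)
    cur_y = np.full(m + 1, neg, dtype=np.int64)
    best = np.int64(0)
    for i in range(1, n + 1):
        qi = qarr[i - 1]
        cur_m[0] = neg
        cur_x[0] = neg
        cur_y[0] = neg
        for j in range(1, m + 1):
            sj = sarr[j - 1]
            step = submat[qi, sj] * r3 + r2 + 1  # score, one column, one q residue
            if qi == sj:
                step += radix  # identity
            diag = prev_m[j - 1]
            if prev_x[j - 1] > diag:
                diag = prev_x[j - 1]
            if prev_y[j - 1] > diag:
                diag = prev_y[j - 1]
            if diag < 0:
                diag = np.int64(0)  # fresh local start
            mval = diag + step
            cur_m[j] = mval
            if mval > best:
                best = mval
            xo = cur_m[j - 1] + open_x
            xe = cur_x[j - 1] + ext_x
            cur_x[j] = xo if xo > xe else xe
            yo = prev_m[j] + open_y
            ye = prev_y[j] + ext_y
            cur_y[j] = yo if yo > ye else ye
        prev_m, cur_m = cur_m, prev_m
        prev_x, cur_x = cur_x, prev_x
        prev_y, cur_y = cur_y, prev_y
    return best


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _sw_dp = njit(cache=False)(_sw_kernel)
except ImportError:  # pragma: no cover
    _sw_dp = _sw_kernel


def _decode(encoded: int, radix: int) -> tuple[int, int, int, int]:
    qcons = encoded % radix
    encoded //= radix
    identities = encoded % radix
    encoded //= radix
    columns = encoded % radix
    encoded //= radix
    return int(encoded), int(columns), int(identities), int(qcons)


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> AlignmentHit:
    """Optimal Smith-Waterman alignment of ``query`` against ``subject``.

    Returns identity over alignment columns and coverage over the query
    span, from the most-columns/most-identities co-optimal alignment. A
    non-positive optimal score (no local similarity) yields identity 0 /
    coverage 0.
    """
    if not query.sequence or not subject.sequence:
        raise ValueError("empty sequence")
    if max(len(query.sequence), len(subject.sequence)) >= _RADIX:
        raise ValueError(f"sequences longer than {_RADIX - 1} residues are not supported")
    submat = _substitution_array(scoring)
    qarr = np.array([_CHAR_INDEX[c] for c in query.sequence], dtype=np.int64)
    sarr = np.array([_CHAR_INDEX[c] for c in subject.sequence], dtype=np.int64)
    encoded = _sw_dp(qarr, sarr, submat, int(scoring.gap_open), int(scoring.gap_extend), _RADIX)
    score, columns, identities, qcons = _decode(int(encoded), _RADIX)
    if score <= 0 or columns == 0:
        return AlignmentHit(query.id, subject.id, 0.0, 0.0, 0.0)
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        identity_pct=100.0 * identities / columns,
        query_coverage_pct=100.0 * qcons / len(query.sequence),
        score=float(score),
    )


def _all_hits(
    target: list[SequenceRecord],
    reference: list[SequenceRecord],
    scoring: AlignmentScoring,
) -> list[AlignmentHit]:
    # query = target protein (coverage is taken over the target sequence)
    return [local_align(t, r, scoring) for t in target for r in reference]


def build_homolog_map(
    target: list[SequenceRecord],
    reference: list[SequenceRecord],
    identity_cutoff_pct: float = 70.0,
    coverage_cutoff_pct: float = 90.0,
    scoring: AlignmentScoring = AlignmentScoring(),
    reciprocal_best: bool = False,
    _hits: list[AlignmentHit] | None = None,
) -> HomologMap:
    """All-vs-all homolog search with identity and coverage thresholds.

    Every above-threshold target homolog of each reference protein is
    retained; ``reciprocal_best=True`` restricts to mutual best-scoring
    hits.
    """
    if not 0 < identity_cutoff_pct <= 100 or not 0 < coverage_cutoff_pct <= 100:
        raise ValueError("cutoffs must lie in (0, 100]")
    hits = _hits if _hits is not None else _all_hits(target, reference, scoring)
    hmap = HomologMap(identity_cutoff_pct, coverage_cutoff_pct)
    passing = [
        h
        for h in hits
        if h.identity_pct >= identity_cutoff_pct and h.query_coverage_pct >= coverage_cutoff_pct
    ]
    if reciprocal_best:
        best_for_target: dict[str, AlignmentHit] = {}
        best_for_ref: dict[str, AlignmentHit] = {}
        for h in passing:
            if h.query_id not in best_for_target or h.score > best_for_target[h.query_id].score:
                best_for_target[h.query_id] = h
            if h.subject_id not in best_for_ref or h.score > best_for_ref[h.subject_id].score:
                best_for_ref[h.subject_id] = h
        passing = [
            h
            for h in passing
            if best_for_target[h.query_id] is h and best_for_ref[h.subject_id] is h
        ]
    for h in passing:
        hmap.add(h.subject_id, h)
    return hmap


def transfer_interactions(
    homolog_map: HomologMap,
    reference_ppis: InteractionTable,
    label: str = "interolog",
) -> InteractionNetwork:
    """Project reference interactions through the homolog map.

    For every reference pair (R1, R2), all target pairs (t1, t2) with
    t1 homologous to R1 and t2 to R2 are predicted; self-interactions and
    duplicates are removed.
    """
    net = InteractionNetwork()
    for r1, r2 in reference_ppis:
        for t1 in homolog_map.targets_of(r1):
            for t2 in homolog_map.targets_of(r2):
                if t1 != t2:
                    net.add_edge(t1, t2, label)
    return net


def cutoff_sweep(
    target: list[SequenceRecord],
    reference: list[SequenceRecord],
    reference_ppis: InteractionTable,
    cutoffs: list[float],
    coverage_cutoff_pct: float = 90.0,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> pd.DataFrame:
    """Predicted-interaction count at each identity cutoff (alignments run once)."""
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    hits = _all_hits(target, reference, scoring)
    rows = []
    for cutoff in cutoffs:
        hmap = build_homolog_map(
            target, reference, cutoff, coverage_cutoff_pct, scoring, _hits=hits
        )
        net = transfer_interactions(hmap, reference_ppis)
        rows.append({"identity_cutoff_pct": cutoff, "predicted_ppis": net.n_edges})
    return pd.DataFrame(rows)
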