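"""Domain-motif interaction prediction (D-MIST-style PSSM matching).

A position-specific scoring matrix (PSSM) describes the binding motif of a
protein domain. Two proteins are predicted to interact when one carries the
domain (profile-HMM annotation with e-value <= cutoff, default 0.01) and the
other matches the domain's motif profile somewhere in its sequence.

Profiles are stored as per-position residue probabilities built from
aligned motif instances:

    score(position, residue) = (q + p) / (N + B)

where q is the observed count of the residue at that position, p its
pseudocount, N the number of instances and B the total pseudocount mass
(default: uniform p = 0.05 per residue, B = 1). Every column therefore sums
to exactly 1.

Scanning slides the profile along a sequence, scoring each window as the sum
of log probabilities and min-max normalising it to [0, 1]:

    normalized = (window - min attainable) / (max attainable - min attainable)

so profiles of different lengths share one threshold scale (default 0.8;
1.0 accepts only consensus-optimal windows). 'X' residues score the column
minimum.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DomainAnnotation, FormatError, RESIDUE_ORDER, SequenceRecord
from .network import InteractionNetwork

_RESIDUE_INDEX = {aa: i for i, aa in enumerate(RESIDUE_ORDER)}


@dataclass(frozen=True)
class PSSM:
    """A motif profile: L x 20 scores in fixed residue order, tied to a domain."""

    motif_id: str
    domain_id: str
    scores: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != len(RESIDUE_ORDER) or scores.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: PSSM must be L x 20 with L >= 1")
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])


@dataclass(frozen=True)
class PssmCounts:
    """Observed counts and pseudocounts underlying a probability PSSM."""

    q: np.ndarray  # L x 20 observed counts
    p: np.ndarray  # L x 20 pseudocounts
    N: float  # number of motif instances
    B: float  # total pseudocount mass per column


@dataclass(frozen=True)
class PssmHit:
    """One above-threshold window of a PSSM scan (1-based start)."""

    protein_id: str
    motif_id: str
    start: int
    window_score: float
    normalized_score: float


def uniform_pseudocounts(length: int, per_residue: float = 0.05) -> np.ndarray:
    """The default pseudocount scheme: a flat ``per_residue`` at every cell."""
    return np.full((length, len(RESIDUE_ORDER)), per_residue, dtype=float)


def build_pssm(
    instances: list[str],
    motif_id: str = "motif",
    domain_id: str = "domain",
    pseudocounts: np.ndarray | float = 0.05,
    return_counts: bool = False,
) -> PSSM | tuple[PSSM, PssmCounts]:
    """Build a probability PSSM from aligned, equal-length, gap-free instances.

    ``pseudocounts`` is either a flat per-residue value or a full L x 20
    array; columns of the resulting matrix sum to 1 exactly.
    """
    if not instances:
        raise ValueError("no motif instances")
    length = len(instances[0])
    if any(len(s) != length for s in instances):
        raise ValueError("motif instances must have equal length")
    q = np.zeros((length, len(RESIDUE_ORDER)), dtype=float)
    for seq in instances:
        for pos, aa in enumerate(seq.upper()):
            if aa not in _RESIDUE_INDEX:
                raise ValueError(f"non-standard residue {aa!r} in motif instance")
            q[pos, _RESIDUE_INDEX[aa]] += 1
    p = (
        uniform_pseudocounts(length, float(pseudocounts))
        if np.isscalar(pseudocounts)
        else np.asarray(pseudocounts, dtype=float)
    )
    if p.shape != q.shape or (p < 0).any():
        raise ValueError("pseudocount array must be non-negative L x 20")
    n_seqs = float(len(instances))
    b_total = float(p[0].sum())
    if not np.allclose(p.sum(axis=1), b_total):
        raise ValueError("pseudocount mass must be equal across positions")
    pssm = PSSM(motif_id, domain_id, (q + p) / (n_seqs + b_total))
    if return_counts:
        return pssm, PssmCounts(q=q, p=p, N=n_seqs, B=b_total)
    return pssm


def scan_pssm(
    pssm: PSSM,
    protein: SequenceRecord,
    threshold: float = 0.8,
    log: bool | None = None,
) -> list[PssmHit]:
    """All windows of ``protein`` whose normalised profile score >= threshold.

    ``log=None`` auto-selects log-space scoring when every matrix entry is
    positive (the probability matrices produced by :func:`build_pssm`);
    matrices with non-positive entries are summed as-is. A degenerate
    profile whose best and worst windows coincide normalises to 1.0.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    length = pssm.length
    seq = protein.sequence
    if len(seq) < length:
        return []
    matrix = pssm.scores
    if log is None:
        log = bool((matrix > 0).all())
    matrix = np.log(matrix) if log else matrix
    col_min = matrix.min(axis=1)
    col_max = matrix.max(axis=1)
    smin = float(col_min.sum())
    smax = float(col_max.sum())
    span = smax - smin
    hits = []
    for start in range(len(seq) - length + 1):
        window = 0.0
        for pos in range(length):
            aa = seq[start + pos]
            idx = _RESIDUE_INDEX.get(aa)
            # 'X' (unknown) scores the column minimum
            window += float(matrix[pos, idx]) if idx is not None else float(col_min[pos])
        normalized = 1.0 if span <= 0 else (window - smin) / span
        if normalized >= threshold - 1e-12:
            hits.append(PssmHit(protein.id, pssm.motif_id, start + 1, window, min(normalized, 1.0)))
    return hits


def predict_dmist(
    target: list[SequenceRecord],
    annotations: list[DomainAnnotation],
    library: list[PSSM],
    e_cutoff: float = 0.01,
    scan_threshold: float = 0.8,
    label: str = "dmist",
) -> InteractionNetwork:
    """Predict domain-side x motif-side interactions over a proteome.

    For each protein X carrying domain D (e-value <= ``e_cutoff``) and each
    protein Y with at least one scan hit against any profile of D, the edge
    (X, Y) is predicted; self-pairs and duplicates are removed.
    """
    domain_side: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.e_value <= e_cutoff:
            domain_side.setdefault(ann.domain_id, set()).add(ann.protein_id)

    motif_side: dict[str, set[str]] = {}
    for pssm in library:
        if pssm.domain_id not in domain_side:
            continue  # no annotated carrier; scan would be wasted
        carriers = motif_side.setdefault(pssm.domain_id, set())
        for protein in target:
            if protein.id in carriers:
                continue
            if scan_pssm(pssm, protein, scan_threshold):
                carriers.add(protein.id)

    net = InteractionNetwork()
    for domain_id, xs in domain_side.items():
        for x in xs:
            for y in motif_side.get(domain_id, ()):
                if x != y:
                    net.add_edge(x, y, label)
    return net


# ---------------------------------------------------------------------------
# library I/O — "#PSSM <motif_id> <domain_id> <length>" then L rows of 20
# ---------------------------------------------------------------------------


def read_pssm_library(path: str | os.PathLike) -> list[PSSM]:
    library = []
    with open(path) as fh:
        lines = [(i, line.strip()) for i, line in enumerate(fh, start=1)]
    lines = [(i, text) for i, text in lines if text]
    pos = 0
    while pos < len(lines):
        lineno, header = lines[pos]
        fields = header.split()
        if fields[0] != "#PSSM" or len(fields) != 4:
            raise FormatError(f"{path}: line {lineno}: expected '#PSSM <motif> <domain> <length>'")
        motif_id, domain_id = fields[1], fields[2]
        try:
            length = int(fields[3])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: bad length {fields[3]!r}") from exc
        rows = []
        for offset in range(length):
            if pos + 1 + offset >= len(lines):
                raise FormatError(f"{path}: {motif_id}: truncated matrix")
            row_lineno, row = lines[pos + 1 + offset]
            values = row.split()
            if len(values) != len(RESIDUE_ORDER):
                raise FormatError(
                    f"{path}: line {row_lineno}: expected {len(RESIDUE_ORDER)} scores, got {len(values)}"
                )
            try:
                rows.append([float(v) for v in values])
            except ValueError as exc:
                raise FormatError(f"{path}: line {row_lineno}: non-numeric score") from exc
        library.append(PSSM(motif_id, domain_id, np.array(rows)))
        pos += 1 + length
    return library


def write_pssm_library(library: list[PSSM], path: str | os.PathLike, precision: int = 10) -> None:
    with open(path, "w") as fh:
        for pssm in library:
            fh.write(f"#PSSM {pssm.motif_id} {pssm.domain_id} {pssm.length}\n")
            for row in pssm.scores:
                fh.write(" ".join(f"{v:.{precision}g}" for v in row) + "\n")
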