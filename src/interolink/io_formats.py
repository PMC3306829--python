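"""Readers and writers for every external file the pipeline touches.

Dialects, all plain text:

* FASTA — standard, wrap-agnostic; sequences uppercased on load.
* Interaction tables — tab-delimited, >=2 columns (idA, idB[, source]);
  unordered, deduplicated; self-pairs optionally dropped.
* SIF — Cytoscape ``idA<TAB>pp<TAB>idB``, smaller id first.
* Domain annotations — ``protein_id<TAB>domain_id<TAB>e_value``.
* Domain pairs (iPfam-style) — ``domain_a<TAB>domain_b``.
* GO annotations (GAF-lite) — ``protein_id<TAB>go_id<TAB>category``.
* Contact records — ``complex_id idA idB seqA seqB contactsA contactsB``
  (tab-delimited; contact lists are comma-separated 1-based residue indices,
  ``-`` for an empty list).
* PSSM library — see :mod:`interolink.dmist` (re-exported here).

All residue/contact coordinates surfaced to users are 1-based inclusive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

from .network import Edge, InteractionNetwork, canonical_pair

#: The 20 standard amino acids in the fixed column order used by PSSM files.
RESIDUE_ORDER = "ACDEFGHIKLMNPQRSTVWY"
#: Accepted sequence alphabet: the 20 standard residues plus 'X' (unknown).
SEQUENCE_ALPHABET = frozenset(RESIDUE_ORDER + "X")

GO_CATEGORIES = ("biological_process", "molecular_function", "cellular_component")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A protein accession plus its amino-acid sequence (uppercase, 20 AA + X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty sequence id")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(f"{self.id!r}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


class InteractionTable:
    """An unordered, deduplicated set of protein-id pairs with source labels."""

    def __init__(self) -> None:
        self._labels: dict[Edge, set[str]] = {}

    def add(self, a: str, b: str, source: str | None = None) -> None:
        key = canonical_pair(a, b)
        labels = self._labels.setdefault(key, set())
        if source is not None:
            labels.add(source)

    @classmethod
    def from_pairs(cls, pairs: Iterable[Edge], source: str | None = None) -> "InteractionTable":
        table = cls()
        for a, b in pairs:
            table.add(a, b, source)
        return table

    @property
    def pairs(self) -> list[Edge]:
        return sorted(self._labels)

    def pair_set(self) -> set[Edge]:
        return set(self._labels)

    def sources(self, a: str, b: str) -> set[str]:
        return set(self._labels[canonical_pair(a, b)])

    def __contains__(self, pair: Edge) -> bool:
        return canonical_pair(*pair) in self._labels

    def __iter__(self) -> Iterator[Edge]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self._labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionTable):
            return NotImplemented
        return self._labels.keys() == other._labels.keys()


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein -> domain assignment with the profile-search e-value."""

    protein_id: str
    domain_id: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value for {self.protein_id}/{self.domain_id}")


class DomainPairSet:
    """A symmetric set of unordered domain-id pairs (iPfam-style)."""

    def __init__(self, pairs: Iterable[Edge] = ()) -> None:
        self._pairs: set[Edge] = {canonical_pair(a, b) for a, b in pairs}

    def add(self, a: str, b: str) -> None:
        self._pairs.add(canonical_pair(a, b))

    def __contains__(self, pair: Edge) -> bool:
        return canonical_pair(*pair) in self._pairs

    @property
    def pairs(self) -> list[Edge]:
        return sorted(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DomainPairSet):
            return NotImplemented
        return self._pairs == other._pairs


@dataclass(frozen=True)
class GOAnnotation:
    """A protein -> GO term assignment in one of the three ontologies."""

    protein_id: str
    go_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in GO_CATEGORIES:
            raise ValueError(f"unknown GO category {self.category!r}")


@dataclass(frozen=True)
class ContactRecord:
    """Interface contacts of one binary complex.

    ``contacts_a``/``contacts_b`` hold 1-based residue indices whose side
    chains contact the partner protein (<4 A, as declared by the upstream
    structure processing that produced the record).
    """

    complex_id: str
    protein_a_id: str
    protein_b_id: str
    sequence_a: str
    sequence_b: str
    contacts_a: frozenset[int] = field(default_factory=frozenset)
    contacts_b: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for contacts, seq, side in (
            (self.contacts_a, self.sequence_a, "A"),
            (self.contacts_b, self.sequence_b, "B"),
        ):
            for i in contacts:
                if not 1 <= i <= len(seq):
                    raise ValueError(
                        f"{self.complex_id}: contact index {i} outside [1, {len(seq)}] on side {side}"
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; empty records raise :class:`FormatError`
    naming the offending line.
    """
    # Locate empty records with line numbers before handing off to SeqIO
    # (SeqIO silently yields zero-length sequences).
    last_header_line = None
    has_seq = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith(">"):
                if last_header_line is not None and not has_seq:
                    raise FormatError(f"{path}: empty sequence for header at line {last_header_line}")
                last_header_line = lineno
                has_seq = False
            elif stripped:
                if last_header_line is None:
                    raise FormatError(f"{path}: sequence data before first header at line {lineno}")
                has_seq = True
    if last_header_line is not None and not has_seq:
        raise FormatError(f"{path}: empty sequence for header at line {last_header_line}")

    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# tabular readers/writers
# ---------------------------------------------------------------------------


def _tab_rows(path: str | os.PathLike, min_cols: int) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise FormatError(f"{path}: line {lineno}: expected >= {min_cols} columns, got {len(cols)}")
            yield lineno, cols


def read_interaction_table(path: str | os.PathLike, drop_self: bool = True) -> InteractionTable:
    """Read a tab-delimited protein-pair table (idA, idB[, source])."""
    table = InteractionTable()
    for _, cols in _tab_rows(path, 2):
        a, b = cols[0], cols[1]
        if drop_self and a == b:
            continue
        table.add(a, b, cols[2] if len(cols) > 2 else None)
    return table


def write_interaction_table(table: InteractionTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in table.pairs:
            sources = sorted(table.sources(a, b))
            fh.write(f"{a}\t{b}" + (f"\t{','.join(sources)}" if sources else "") + "\n")


def write_network_edgelist(
    network: InteractionNetwork, path: str | os.PathLike, format: str = "tsv"
) -> None:
    """Write a network as Cytoscape SIF or as TSV with a support-count column."""
    if format not in ("sif", "tsv"):
        raise ValueError(f"unknown edge-list format {format!r}")
    with open(path, "w") as fh:
        for a, b in network.edges:
            if format == "sif":
                fh.write(f"{a}\tpp\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{len(network.support(a, b))}\n")


def read_domain_annotations(path: str | os.PathLike) -> list[DomainAnnotation]:
    out = []
    for lineno, cols in _tab_rows(path, 3):
        try:
            out.append(DomainAnnotation(cols[0], cols[1], float(cols[2])))
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_domain_annotations(annotations: Iterable[DomainAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            fh.write(f"{ann.protein_id}\t{ann.domain_id}\t{ann.e_value:g}\n")


def read_domain_pairs(path: str | os.PathLike) -> DomainPairSet:
    pairs = DomainPairSet()
    for _, cols in _tab_rows(path, 2):
        pairs.add(cols[0], cols[1])
    return pairs


def write_domain_pairs(pairs: DomainPairSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in pairs.pairs:
            fh.write(f"{a}\t{b}\n")


def read_go_annotations(path: str | os.PathLike) -> list[GOAnnotation]:
    out = []
    for lineno, cols in _tab_rows(path, 3):
        try:
            out.append(GOAnnotation(cols[0], cols[1], cols[2]))
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_go_annotations(annotations: Iterable[GOAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            fh.write(f"{ann.protein_id}\t{ann.go_id}\t{ann.category}\n")


def _format_contacts(contacts: frozenset[int]) -> str:
    return ",".join(str(i) for i in sorted(contacts)) if contacts else "-"


def _parse_contacts(text: str, path, lineno: int) -> frozenset[int]:
    text = text.strip()
    if text in ("", "-"):
        return frozenset()
    try:
        return frozenset(int(tok) for tok in text.split(","))
    except ValueError as exc:
        raise FormatError(f"{path}: line {lineno}: bad contact list {text!r}") from exc


def read_contact_records(path: str | os.PathLike) -> list[ContactRecord]:
    out = []
    for lineno, cols in _tab_rows(path, 7):
        try:
            out.append(
                ContactRecord(
                    complex_id=cols[0],
                    protein_a_id=cols[1],
                    protein_b_id=cols[2],
                    sequence_a=cols[3],
                    sequence_b=cols[4],
                    contacts_a=_parse_contacts(cols[5], path, lineno),
                    contacts_b=_parse_contacts(cols[6], path, lineno),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_contact_records(records: Iterable[ContactRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                "\t".join(
                    (
                        rec.complex_id,
                        rec.protein_a_id,
                        rec.protein_b_id,
                        rec.sequence_a,
                        rec.sequence_b,
                        _format_contacts(rec.contacts_a),
                        _format_contacts(rec.contacts_b),
                    )
                )
                + "\n"
            )


# PSSM library I/O lives next to the PSSM type; re-exported for a single
# import surface over all file dialects.
def read_pssm_library(path: str | os.PathLike):
    from .dmist import read_pssm_library as _read

    return _read(path)


def write_pssm_library(library, path: str | os.PathLike) -> None:
    from .dmist import write_pssm_library as _write

    _write(library, path)
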