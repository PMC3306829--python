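"""The validation battery for predicted interaction networks.

Three orthogonal checks:

* **Domain-pair support** — how many predicted edges join proteins whose
  annotated domains (e-value <= 0.01) form a known interacting domain pair
  (iPfam-style), compared against networks of random protein pairs drawn
  with replacement (100 repetitions in the original protocol).
* **GO-term sharing** — the fraction of edges whose endpoints share at
  least one GO term in any of the three ontologies, against the same null
  (10,000 repetitions in the original protocol).
* **Gold-standard evaluation** — confusion counts against positive (GSP)
  and negative (GSN) pair sets; accuracy = (TP+TN)/(TP+TN+FP+FN) and
  precision = the mean of the PPI precision TP/(TP+FP) and the non-PPI
  precision TN/(TN+FN).

Empirical p-values follow the plain exceedance convention
p = #(null >= observed) / reps, printed to three decimals so a
never-exceeded observation reads "0.000"; the add-one (Davison-Hinkley)
variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_formats import DomainAnnotation, DomainPairSet, GOAnnotation, InteractionTable
from .network import Edge, InteractionNetwork, canonical_pair


@dataclass(frozen=True)
class RandomizationResult:
    observed_statistic: float
    null_samples: tuple[float, ...]
    empirical_p: float
    reps: int
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_samples))

    def formatted_p(self) -> str:
        return f"{self.empirical_p:.3f}"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class GoldStandardResult:
    confusion: ConfusionCounts
    accuracy: float
    precision: float | None
    precision_ppi: float | None
    precision_non_ppi: float | None
    flags: tuple[str, ...] = ()


@dataclass
class ValidationReport:
    """All validation statistics for one method's predicted network."""

    method: str
    ipfam_supported_count: int | None = None
    ipfam_null: RandomizationResult | None = None
    go_sharing_fraction: float | None = None
    go_null: RandomizationResult | None = None
    gold: GoldStandardResult | None = None

    def to_dict(self) -> dict:
        out: dict = {"method": self.method}
        if self.ipfam_supported_count is not None:
            out["ipfam_supported_count"] = self.ipfam_supported_count
        if self.ipfam_null is not None:
            out["ipfam_null_mean"] = round(self.ipfam_null.null_mean, 6)
            out["ipfam_empirical_p"] = self.ipfam_null.formatted_p()
        if self.go_sharing_fraction is not None:
            out["go_sharing_pct"] = round(100.0 * self.go_sharing_fraction, 6)
        if self.go_null is not None:
            out["go_null_mean_pct"] = round(100.0 * self.go_null.null_mean, 6)
            out["go_empirical_p"] = self.go_null.formatted_p()
        if self.gold is not None:
            c = self.gold.confusion
            out["confusion"] = {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
            out["accuracy_pct"] = round(100.0 * self.gold.accuracy, 6)
            if self.gold.precision is not None:
                out["precision_pct"] = round(100.0 * self.gold.precision, 6)
            if self.gold.flags:
                out["flags"] = list(self.gold.flags)
        return out


# ---------------------------------------------------------------------------
# domain-pair (iPfam-style) support
# ---------------------------------------------------------------------------


def _domains_by_protein(
    annotations: Sequence[DomainAnnotation], e_cutoff: float
) -> dict[str, set[str]]:
    by_protein: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.e_value <= e_cutoff:
            by_protein.setdefault(ann.protein_id, set()).add(ann.domain_id)
    return by_protein


def _pair_supported(a: str, b: str, domains: dict[str, set[str]], ipfam: DomainPairSet) -> bool:
    for da in domains.get(a, ()):
        for db in domains.get(b, ()):
            if (da, db) in ipfam:
                return True
    return False


def count_pairs_ipfam_supported(
    pairs: Sequence[Edge],
    annotations: Sequence[DomainAnnotation],
    ipfam: DomainPairSet,
    e_cutoff: float = 0.01,
) -> int:
    """Count pairs whose endpoint domains form a known interacting pair."""
    domains = _domains_by_protein(annotations, e_cutoff)
    return sum(1 for a, b in pairs if _pair_supported(a, b, domains, ipfam))


def count_ipfam_supported(
    net: InteractionNetwork,
    annotations: Sequence[DomainAnnotation],
    ipfam: DomainPairSet,
    e_cutoff: float = 0.01,
) -> int:
    return count_pairs_ipfam_supported(net.edges, annotations, ipfam, e_cutoff)


# ---------------------------------------------------------------------------
# randomized-pair null model
# ---------------------------------------------------------------------------


def draw_random_pairs(
    proteome_ids: Sequence[str], n_pairs: int, rng: np.random.Generator
) -> list[Edge]:
    """Draw unordered protein pairs uniformly with replacement; self-pairs redrawn."""
    if len(proteome_ids) < 2:
        raise ValueError("need at least two proteins to draw pairs")
    ids = list(proteome_ids)
    pairs: list[Edge] = []
    while len(pairs) < n_pairs:
        i, j = rng.integers(0, len(ids), size=2)
        if i == j:
            continue
        pairs.append(canonical_pair(ids[i], ids[j]))
    return pairs


def random_pair_null(
    proteome_ids: Sequence[str],
    n_pairs: int,
    reps: int,
    statistic: Callable[[list[Edge]], float],
    observed: float,
    seed: int,
    add_one: bool = False,
) -> RandomizationResult:
    """Empirical exceedance p-value of ``observed`` against random-pair networks.

    Each repetition draws ``n_pairs`` unordered pairs with replacement from
    the proteome and evaluates ``statistic`` on them.
    """
    if n_pairs < 1 or reps < 1:
        raise ValueError("n_pairs and reps must be >= 1")
    rng = np.random.default_rng(seed)
    null = [float(statistic(draw_random_pairs(proteome_ids, n_pairs, rng))) for _ in range(reps)]
    exceed = sum(1 for v in null if v >= observed)
    p = (exceed + 1) / (reps + 1) if add_one else exceed / reps
    return RandomizationResult(
        observed_statistic=float(observed),
        null_samples=tuple(null),
        empirical_p=p,
        reps=reps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# GO-term sharing
# ---------------------------------------------------------------------------


def _go_by_protein(go: Sequence[GOAnnotation]) -> dict[str, set[str]]:
    by_protein: dict[str, set[str]] = {}
    for ann in go:
        by_protein.setdefault(ann.protein_id, set()).add(ann.go_id)
    return by_protein


def pair_sharing_fraction(
    pairs: Sequence[Edge],
    go_by_protein: dict[str, set[str]],
    include_unannotated: bool = True,
) -> float:
    """Fraction of pairs whose endpoints share >= 1 GO term (any ontology)."""
    if include_unannotated:
        considered = list(pairs)
    else:
        considered = [
            (a, b) for a, b in pairs if a in go_by_protein and b in go_by_protein
        ]
    if not considered:
        raise ValueError("sharing fraction undefined for an empty pair set")
    shared = sum(
        1
        for a, b in considered
        if go_by_protein.get(a, set()) & go_by_protein.get(b, set())
    )
    return shared / len(considered)


def go_sharing_fraction(
    net: InteractionNetwork,
    go: Sequence[GOAnnotation],
    include_unannotated: bool = True,
) -> float:
    if net.n_edges == 0:
        raise ValueError("sharing fraction undefined for an empty network")
    return pair_sharing_fraction(net.edges, _go_by_protein(go), include_unannotated)


# ---------------------------------------------------------------------------
# gold-standard evaluation
# ---------------------------------------------------------------------------


def evaluate_against_gold(
    predicted: InteractionNetwork,
    gsp: InteractionTable,
    gsn: InteractionTable,
) -> GoldStandardResult:
    """Confusion counts, accuracy, and class-averaged precision vs GSP/GSN."""
    gsp_pairs = gsp.pair_set()
    gsn_pairs = gsn.pair_set()
    if gsp_pairs & gsn_pairs:
        raise ValueError("gold-standard positive and negative sets overlap")
    predicted_pairs = predicted.edge_set()
    tp = len(gsp_pairs & predicted_pairs)
    fn = len(gsp_pairs) - tp
    fp = len(gsn_pairs & predicted_pairs)
    tn = len(gsn_pairs) - fp
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total if total else 0.0
    flags = []
    precision_ppi = tp / (tp + fp) if (tp + fp) else None
    if precision_ppi is None:
        flags.append("ppi_precision_undefined")
    precision_non = tn / (tn + fn) if (tn + fn) else None
    if precision_non is None:
        flags.append("non_ppi_precision_undefined")
    defined = [v for v in (precision_ppi, precision_non) if v is not None]
    precision = sum(defined) / len(defined) if defined else None
    return GoldStandardResult(
        confusion=ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn),
        accuracy=accuracy,
        precision=precision,
        precision_ppi=precision_ppi,
        precision_non_ppi=precision_non,
        flags=tuple(flags),
    )


def generate_gsn(
    proteome_ids: Sequence[str],
    n_pairs: int,
    gsp: InteractionTable,
    seed: int,
    exclude: Sequence[Edge] = (),
) -> InteractionTable:
    """Uniform random pairs excluding the GSP (and any extra excluded pairs)."""
    rng = np.random.default_rng(seed)
    forbidden = gsp.pair_set() | {canonical_pair(a, b) for a, b in exclude}
    chosen: set[Edge] = set()
    attempts = 0
    while len(chosen) < n_pairs:
        attempts += 1
        if attempts > 1000 * n_pairs:
            raise ValueError("could not draw enough negative pairs")
        pair = draw_random_pairs(proteome_ids, 1, rng)[0]
        if pair not in forbidden:
            chosen.add(pair)
    return InteractionTable.from_pairs(sorted(chosen), source="gsn")


# ---------------------------------------------------------------------------
# convenience: the full battery for one network
# ---------------------------------------------------------------------------


def validate_network(
    net: InteractionNetwork,
    method: str,
    proteome_ids: Sequence[str],
    annotations: Sequence[DomainAnnotation] | None = None,
    ipfam: DomainPairSet | None = None,
    go: Sequence[GOAnnotation] | None = None,
    gsp: InteractionTable | None = None,
    gsn: InteractionTable | None = None,
    e_cutoff: float = 0.01,
    reps_ipfam: int = 100,
    reps_go: int = 100,
    seed: int = 0,
) -> ValidationReport:
    report = ValidationReport(method=method)
    if net.n_edges == 0:
        return report
    if annotations is not None and ipfam is not None:
        observed = count_ipfam_supported(net, annotations, ipfam, e_cutoff)
        report.ipfam_supported_count = observed
        report.ipfam_null = random_pair_null(
            proteome_ids,
            net.n_edges,
            reps_ipfam,
            lambda pairs: count_pairs_ipfam_supported(pairs, annotations, ipfam, e_cutoff),
            observed=observed,
            seed=seed,
        )
    if go is not None:
        go_by_protein = _go_by_protein(go)
        observed_frac = go_sharing_fraction(net, go)
        report.go_sharing_fraction = observed_frac
        report.go_null = random_pair_null(
            proteome_ids,
            net.n_edges,
            reps_go,
            lambda pairs: pair_sharing_fraction(pairs, go_by_protein),
            observed=observed_frac,
            seed=seed + 1,
        )
    if gsp is not None and gsn is not None:
        report.gold = evaluate_against_gold(net, gsp, gsn)
    return report
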