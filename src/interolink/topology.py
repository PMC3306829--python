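"""Network merging and the topology-metric suite.

Conventions (chosen to match the Cytoscape-style analyses common for
protein-interaction networks):

* betweenness is computed within each connected component and normalised by
  (N-1)(N-2)/2, N the component size, so values lie in [0, 1];
* closeness is the reciprocal of the mean shortest-path length to the other
  nodes of the component (isolated nodes score 0);
* clustering is 2 e_n / (k_n (k_n - 1)), zero for degree < 2; the network
  average is taken over all nodes;
* the topological coefficient of n averages J(n, m) — shared neighbours of
  n and m, plus one if n-m is an edge — over all m sharing at least one
  neighbour with n, divided by the degree of n;
* the degree-distribution power law P(k) ~ k^-gamma is fitted by weighted
  least squares of log10 P(k) on log10 k with weights n_k (each node counts
  once). Unweighted regression on the raw histogram is badly flattened by
  sporadic single-node counts in the tail, underestimating gamma by far
  more than its sampling error; per-node weighting removes that bias while
  still using raw, un-binned points. Zero-count degrees (and degree 0) are
  excluded, their logarithm being undefined.

Shortest-path aggregates: the diameter is the largest finite eccentricity,
the radius the smallest eccentricity within the largest component, the
characteristic path length the mean over connected (finite) pairs, and the
connected-pair fraction the share of all unordered node pairs that are
connected at all.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import InteractionNetwork


class UndefinedFitError(ValueError):
    """Raised when a power-law fit has fewer than two usable points."""


@dataclass
class DegreeDistribution:
    """degree k -> number of nodes n_k, with P(k) = n_k / total nodes."""

    counts: dict[int, int]

    @property
    def total_nodes(self) -> int:
        return sum(self.counts.values())

    def probability(self, k: int) -> float:
        return self.counts.get(k, 0) / self.total_nodes


@dataclass(frozen=True)
class PowerLawFit:
    """P(k) ~ k^-exponent fitted on log-log axes."""

    exponent: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class TopologySummary:
    node_count: int
    edge_count: int
    avg_clustering_coefficient: float
    diameter: int
    radius: int
    connected_pair_fraction: float
    characteristic_path_length: float
    avg_neighbors: float
    path_length_histogram: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "node_count": self.node_count,
            "edge_count": self.edge_count,
            "avg_clustering_coefficient": self.avg_clustering_coefficient,
            "diameter": self.diameter,
            "radius": self.radius,
            "connected_pair_fraction": self.connected_pair_fraction,
            "connected_pair_pct": 100.0 * self.connected_pair_fraction,
            "characteristic_path_length": self.characteristic_path_length,
            "avg_neighbors": self.avg_neighbors,
            "path_length_histogram": {str(k): v for k, v in sorted(self.path_length_histogram.items())},
        }


def merge_networks(nets: list[InteractionNetwork]) -> InteractionNetwork:
    """Edge and node union; per-edge support is the union of method labels."""
    if not nets:
        raise ValueError("nothing to merge")
    merged = InteractionNetwork()
    for net in nets:
        for node in net.nodes:
            merged.add_node(node)
        for a, b in net.edges:
            labels = net.support(a, b) or {"unlabelled"}
            for label in labels:
                merged.add_edge(a, b, label)
    return merged


def degree_distribution(net: InteractionNetwork) -> DegreeDistribution:
    g = net.to_networkx()
    return DegreeDistribution(dict(Counter(d for _, d in g.degree())))


def fit_power_law(dist: DegreeDistribution, weighted: bool = True) -> PowerLawFit:
    """Fit log10 P(k) = -gamma log10 k + c by (count-weighted) least squares."""
    ks = np.array(sorted(k for k, n in dist.counts.items() if k > 0 and n > 0))
    if len(ks) < 2:
        raise UndefinedFitError("need >= 2 distinct positive degrees with nodes")
    nk = np.array([dist.counts[int(k)] for k in ks], dtype=float)
    total = dist.total_nodes
    x = np.log10(ks.astype(float))
    y = np.log10(nk / total)
    w = nk if weighted else np.ones_like(nk)
    sw = np.sqrt(w)
    design = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    slope, intercept = coef
    resid = y - (slope * x + intercept)
    ybar = np.average(y, weights=w)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    if ss_tot <= 1e-300:
        r_squared = 1.0 if ss_res <= 1e-12 else 0.0
    else:
        r_squared = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return PowerLawFit(exponent=-float(slope), r_squared=r_squared, n_points=len(ks))


def _components(g: nx.Graph) -> list[set]:
    return [set(c) for c in nx.connected_components(g)]


def betweenness_centrality(net: InteractionNetwork) -> dict[str, float]:
    """Per-component betweenness, normalised by (N-1)(N-2)/2 of the component."""
    g = net.to_networkx()
    out: dict[str, float] = {}
    for comp in _components(g):
        sub = g.subgraph(comp)
        out.update(nx.betweenness_centrality(sub, normalized=True))
    return out


def closeness_centrality(net: InteractionNetwork) -> dict[str, float]:
    """1 / mean shortest-path length to the other nodes of the component."""
    g = net.to_networkx()
    return {n: float(c) for n, c in nx.closeness_centrality(g, wf_improved=False).items()}


def clustering_coefficient(net: InteractionNetwork) -> dict[str, float]:
    g = net.to_networkx()
    return {n: float(c) for n, c in nx.clustering(g).items()}


def topological_coefficient(net: InteractionNetwork) -> dict[str, float]:
    """T_n = avg_m J(n, m) / k_n over nodes m sharing >= 1 neighbour with n."""
    g = net.to_networkx()
    out: dict[str, float] = {}
    adj = {n: set(g.neighbors(n)) for n in g.nodes}
    for n in g.nodes:
        k_n = len(adj[n])
        if k_n == 0:
            out[n] = 0.0
            continue
        j_values = []
        for m in g.nodes:
            if m == n:
                continue
            shared = len(adj[n] & adj[m])
            if shared >= 1:
                j_values.append(shared + (1 if m in adj[n] else 0))
        out[n] = (sum(j_values) / len(j_values)) / k_n if j_values else 0.0
    return out


def path_statistics(net: InteractionNetwork) -> TopologySummary:
    """All-pairs shortest-path aggregates plus clustering/degree summaries."""
    g = net.to_networkx()
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    histogram: Counter[int] = Counter()
    eccentricities: dict[str, int] = {}
    finite_pair_count = 0
    finite_length_sum = 0
    components = sorted(_components(g), key=lambda c: (-len(c), min(c) if c else ""))
    for comp in components:
        sub = g.subgraph(comp)
        for source, lengths in nx.all_pairs_shortest_path_length(sub):
            positive = [d for m, d in lengths.items() if m != source]
            eccentricities[source] = max(positive) if positive else 0
            for m, d in lengths.items():
                if m > source:  # unordered pairs once
                    histogram[d] += 1
                    finite_pair_count += 1
                    finite_length_sum += d
    total_pairs = n_nodes * (n_nodes - 1) // 2
    diameter = max(eccentricities.values(), default=0)
    largest = components[0] if components else set()
    radius = min((eccentricities[n] for n in largest), default=0)
    return TopologySummary(
        node_count=n_nodes,
        edge_count=n_edges,
        avg_clustering_coefficient=(
            float(np.mean(list(nx.clustering(g).values()))) if n_nodes else 0.0
        ),
        diameter=diameter,
        radius=radius,
        connected_pair_fraction=(finite_pair_count / total_pairs) if total_pairs else 0.0,
        characteristic_path_length=(
            finite_length_sum / finite_pair_count if finite_pair_count else 0.0
        ),
        avg_neighbors=(2.0 * n_edges / n_nodes) if n_nodes else 0.0,
        path_length_histogram=dict(histogram),
    )
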