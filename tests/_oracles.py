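"""Independent brute-force oracles used to check the library implementations.

Everything here is deliberately naive: plain loops, plain tuples, regexes,
dense matrices. None of it shares code with the package.
"""

from __future__ import annotations

import math
import re
from itertools import combinations

import numpy as np

NEG = (-(10**9), 0, 0, 0)


def sw_tuple_dp(query: str, subject: str, score_fn, gap_open: int, gap_extend: int):
    """Affine local alignment maximising (score, columns, identities, q-used).

    Transparent tuple arithmetic over three explicit state tables; no
    encoding, no rolling rows. Returns the best tuple, or (0, 0, 0, 0) when
    no positive-scoring alignment exists.
    """
    n, m = len(query), len(subject)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = (0, 0, 0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            a, b = query[i - 1], subject[j - 1]
            step = (score_fn(a, b), 1, 1 if a == b else 0, 1)
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], (0, 0, 0, 0))
            M[i][j] = tuple(p + s for p, s in zip(prev, step))
            xo = (M[i][j - 1][0] - gap_open, M[i][j - 1][1] + 1, M[i][j - 1][2], M[i][j - 1][3])
            xe = (X[i][j - 1][0] - gap_extend, X[i][j - 1][1] + 1, X[i][j - 1][2], X[i][j - 1][3])
            X[i][j] = max(xo, xe)
            yo = (M[i - 1][j][0] - gap_open, M[i - 1][j][1] + 1, M[i - 1][j][2], M[i - 1][j][3] + 1)
            ye = (Y[i - 1][j][0] - gap_extend, Y[i - 1][j][1] + 1, Y[i - 1][j][2], Y[i - 1][j][3] + 1)
            Y[i][j] = max(yo, ye)
            best = max(best, M[i][j])
    return best if best[0] > 0 else (0, 0, 0, 0)


def sw_enumerate_paths(query: str, subject: str, score_fn, gap_open: int, gap_extend: int):
    """Exhaustive DFS over every local alignment path (tiny inputs only).

    Every monotone path of match/gap columns from every start cell is
    walked; flanking gap columns are excluded by construction (paths start
    and end with a residue-vs-residue column). Returns the best
    (score, columns, identities, query-used) tuple.
    """
    n, m = len(query), len(subject)
    best = (0, 0, 0, 0)

    def walk(i, j, score, cols, ids, qused, state):
        nonlocal best
        if i < n and j < m:
            a, b = query[i], subject[j]
            s2 = score + score_fn(a, b)
            t = (s2, cols + 1, ids + (1 if a == b else 0), qused + 1)
            if t[0] > 0:
                best = max(best, t)
            walk(i + 1, j + 1, *t, "M")
        if j < m:  # gap in query
            s2 = score - (gap_open if state != "X" else gap_extend)
            walk(i, j + 1, s2, cols + 1, ids, qused, "X")
        if i < n:  # gap in subject
            s2 = score - (gap_open if state != "Y" else gap_extend)
            walk(i + 1, j, s2, cols + 1, ids, qused + 1, "Y")

    for i0 in range(n):
        for j0 in range(m):
            walk(i0, j0, 0, 0, 0, 0, "M")
    return best


def pssm_window_scores(matrix: np.ndarray, residue_order: str, sequence: str):
    """Per-window (start_1based, raw, normalized) by direct per-cell lookups."""
    length = matrix.shape[0]
    use_log = bool((matrix > 0).all())
    cells = [[math.log(v) for v in row] if use_log else list(row) for row in matrix]
    col_min = [min(row) for row in cells]
    col_max = [max(row) for row in cells]
    smin, smax = sum(col_min), sum(col_max)
    out = []
    for start in range(len(sequence) - length + 1):
        raw = 0.0
        for pos in range(length):
            aa = sequence[start + pos]
            raw += cells[pos][residue_order.index(aa)] if aa in residue_order else col_min[pos]
        norm = 1.0 if smax - smin <= 0 else (raw - smin) / (smax - smin)
        out.append((start + 1, raw, norm))
    return out


def motif_segments_regex(mask: str):
    """Maximal segments of a contact mask ('1' contact) bridging <=2 zeros.

    Returns (start_1based, end_1based) for segments spanning >= 5 residues.
    """
    return [
        (m.start() + 1, m.end())
        for m in re.finditer(r"1(?:0{1,2}1|1)*", mask)
        if m.end() - m.start() >= 5
    ]


# ---------------------------------------------------------------------------
# graph metrics on an adjacency structure {node: set(neighbours)}
# ---------------------------------------------------------------------------


def _bfs_dist(adj, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _path_counts(adj, source, dist):
    """sigma[source -> v]: number of shortest paths, by BFS-order DP."""
    sigma = {v: 0 for v in dist}
    sigma[source] = 1
    for v in sorted(dist, key=dist.get):
        for w in adj[v]:
            if w in dist and dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return sigma


def betweenness_brute(adj):
    """Pair-by-pair shortest-path counting, normalised per component."""
    nodes = sorted(adj)
    comp_of = {}
    for node in nodes:
        if node not in comp_of:
            comp = set(_bfs_dist(adj, node))
            for member in comp:
                comp_of[member] = frozenset(comp)
    dist = {u: _bfs_dist(adj, u) for u in nodes}
    sigma = {u: _path_counts(adj, u, dist[u]) for u in nodes}
    result = {u: 0.0 for u in nodes}
    for s, t in combinations(nodes, 2):
        if t not in dist[s]:
            continue
        d_st = dist[s][t]
        total = sigma[s][t]
        for n in comp_of[s]:
            if n in (s, t):
                continue
            if dist[s].get(n, -1) + dist[n].get(t, -1) == d_st:
                result[n] += sigma[s][n] * sigma[n][t] / total
    for n in nodes:
        size = len(comp_of[n])
        norm = (size - 1) * (size - 2) / 2
        result[n] = result[n] / norm if norm > 0 else 0.0
    return result


def closeness_brute(adj):
    out = {}
    for u in sorted(adj):
        dist = _bfs_dist(adj, u)
        others = [d for v, d in dist.items() if v != u]
        out[u] = len(others) / sum(others) if others and sum(others) else 0.0
    return out


def clustering_brute(adj):
    out = {}
    for u in sorted(adj):
        nbrs = sorted(adj[u])
        k = len(nbrs)
        if k < 2:
            out[u] = 0.0
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if b in adj[a])
        out[u] = 2.0 * links / (k * (k - 1))
    return out


def topological_coeff_brute(adj):
    """Via the squared adjacency matrix: A2[n,m] = shared neighbours."""
    nodes = sorted(adj)
    index = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=int)
    for u in nodes:
        for v in adj[u]:
            a[index[u], index[v]] = 1
    a2 = a @ a
    out = {}
    for u in nodes:
        i = index[u]
        k = int(a[i].sum())
        if k == 0:
            out[u] = 0.0
            continue
        js = []
        for v in nodes:
            j = index[v]
            if v != u and a2[i, j] >= 1:
                js.append(a2[i, j] + a[i, j])
        out[u] = (sum(js) / len(js)) / k if js else 0.0
    return out


def path_stats_brute(adj):
    """Floyd-Warshall aggregates: diameter, radius (largest component),
    characteristic path length, connected-pair fraction, histogram."""
    nodes = sorted(adj)
    n = len(nodes)
    index = {u: i for i, u in enumerate(nodes)}
    inf = float("inf")
    d = np.full((n, n), inf)
    np.fill_diagonal(d, 0.0)
    for u in nodes:
        for v in adj[u]:
            d[index[u], index[v]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    finite = []
    histogram = {}
    for i, j in combinations(range(n), 2):
        if d[i, j] < inf:
            length = int(d[i, j])
            finite.append(length)
            histogram[length] = histogram.get(length, 0) + 1
    ecc = {}
    for i, u in enumerate(nodes):
        reach = [int(d[i, j]) for j in range(n) if j != i and d[i, j] < inf]
        ecc[u] = max(reach) if reach else 0
    comps = []
    seen = set()
    for u in nodes:
        if u not in seen:
            comp = set(_bfs_dist(adj, u))
            seen |= comp
            comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    largest = comps[0] if comps else set()
    total_pairs = n * (n - 1) // 2
    return {
        "diameter": max(ecc.values(), default=0),
        "radius": min((ecc[u] for u in largest), default=0),
        "characteristic_path_length": (sum(finite) / len(finite)) if finite else 0.0,
        "connected_pair_fraction": (len(finite) / total_pairs) if total_pairs else 0.0,
        "histogram": histogram,
    }


# ---------------------------------------------------------------------------
# prediction-rule enumeration
# ---------------------------------------------------------------------------


def dmist_rule_brute(proteins, annotations, pssm_consensus_hits, e_cutoff):
    """Edges by direct double loop: X has domain D (e <= cutoff), Y hits a
    profile of D. ``pssm_consensus_hits`` maps protein id -> set of domain
    ids whose profile matched (precomputed by any scan)."""
    edges = set()
    ids = [p.id for p in proteins]
    for x in ids:
        domains = {a.domain_id for a in annotations if a.protein_id == x and a.e_value <= e_cutoff}
        for y in ids:
            if x == y:
                continue
            if domains & pssm_consensus_hits.get(y, set()):
                edges.add(tuple(sorted((x, y))))
    return edges


def mmist_rule_brute(proteins, group_pairs):
    """Edges by direct loop over (group pair, ordered protein pair).

    ``group_pairs`` is a list of (motifs1, motifs2) sequence-set pairs.
    """
    edges = set()
    for motifs1, motifs2 in group_pairs:
        for p1 in proteins:
            for p2 in proteins:
                if p1.id == p2.id:
                    continue
                if all(m in p1.sequence for m in motifs1) and all(
                    m in p2.sequence for m in motifs2
                ):
                    edges.add(tuple(sorted((p1.id, p2.id))))
    return edges
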