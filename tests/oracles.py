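"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: a pure-Python affine-gap
Smith-Waterman DP, an exhaustive enumeration of local alignments for tiny
sequences, and direct Floyd-Warshall-based graph statistics.
"""

from __future__ import annotations

import math
from itertools import combinations


def sw_affine_score(a: str, b: str, matrix, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Plain three-matrix Smith-Waterman with affine gaps.

    The first gap position costs gap_open + gap_extend, matching BLAST.
    Returns the best local score (>= 0).
    """
    m, n = len(a), len(b)
    NEG = float("-inf")
    first = gap_open + gap_extend
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (consume b)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - first)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - first)
            diag = H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def _enumerate_global(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Max score over every global alignment of a vs b (exhaustive recursion)."""
    first = gap_open + gap_extend
    best = [float("-inf")]

    def rec(i: int, j: int, score: float, state: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if state == "d" else first), "d")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if state == "i" else first), "i")

    rec(0, 0, 0.0, "m")
    return best[0]


def sw_enumerate_score(a: str, b: str, matrix, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Exhaustive local alignment score: max over all substring pairs of the
    exhaustively enumerated global score (0 when nothing scores positive).
    Only feasible for very short sequences."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = _enumerate_global(a[i1:i2], b[j1:j2], matrix, gap_open, gap_extend)
                    best = max(best, s)
    return int(best)


def graph_stats(n: int, edges: list[tuple[int, int]]) -> dict:
    """Direct computation of every metric the package reports, from an
    adjacency list via Floyd-Warshall. Nodes are 0..n-1."""
    adj = {i: set() for i in range(n)}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    k = sum(len(s) for s in adj.values()) // 2
    deg = {i: len(adj[i]) for i in range(n)}

    INF = math.inf
    dist = [[0 if i == j else (1 if j in adj[i] else INF) for j in range(n)] for i in range(n)]
    for mid in range(n):
        for i in range(n):
            dmi = dist[i][mid]
            if dmi == INF:
                continue
            for j in range(n):
                alt = dmi + dist[mid][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt

    # components by reachability
    comp_of = {}
    comps = []
    for i in range(n):
        if i in comp_of:
            continue
        comp = {j for j in range(n) if dist[i][j] < INF}
        comps.append(comp)
        for j in comp:
            comp_of[j] = len(comps) - 1

    clustering = {}
    for i in range(n):
        if deg[i] < 2:
            clustering[i] = 0.0
            continue
        links = sum(1 for u, v in combinations(adj[i], 2) if v in adj[u])
        clustering[i] = 2.0 * links / (deg[i] * (deg[i] - 1))

    neigh = {
        i: (sum(deg[j] for j in adj[i]) / deg[i] if deg[i] else 0.0) for i in range(n)
    }
    closeness = {}
    for i in range(n):
        reach = [dist[i][j] for j in range(n) if j != i and dist[i][j] < INF]
        closeness[i] = len(reach) / sum(reach) if reach else 0.0

    finite = [(i, j) for i in range(n) for j in range(n) if i != j and dist[i][j] < INF]
    cpl = sum(dist[i][j] for i, j in finite) / len(finite) if finite else 0.0
    kmax = max(deg.values()) if n else 0
    return {
        "n_nodes": n,
        "n_edges": k,
        "avg_degree": 2.0 * k / n if n else 0.0,
        "density": 2.0 * k / (n * (n - 1)) if n > 1 else 0.0,
        "n_components": len(comps),
        "n_isolated": sum(1 for i in range(n) if deg[i] == 0),
        "avg_clustering": sum(clustering.values()) / n if n else 0.0,
        "char_path_length": cpl,
        "connected_pair_pct": 100.0 * len(finite) / (n * (n - 1)) if n > 1 else 0.0,
        "centralization": (
            sum(kmax - d for d in deg.values()) / ((n - 1) * (n - 2)) if n > 2 else 0.0
        ),
        "degree": deg,
        "clustering": clustering,
        "neighborhood_connectivity": neigh,
        "closeness": closeness,
        "components": comps,
    }
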