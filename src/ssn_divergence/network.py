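"""Thresholded sequence similarity network (SSN) and its topology statistics.

The SSN is an undirected ``networkx.Graph``: nodes are sequence ids (annotated
with family and habitat), and an edge joins two sequences when any pairwise hit
in either direction has an E-value at or below the cutoff (default 1e-30).
Every record becomes a node, so sequences too diverged to align to anything
remain in the network as isolated nodes — the diversification signal.

Global statistics follow the conventions:
    average degree  k_bar = 2K / N
    density         D     = 2K / (N (N - 1))
with K the number of edges and N the number of nodes.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .align import AlignmentHit
from .records import ProteinRecord


def length_filter(records: Sequence[ProteinRecord], min_aa: int = 150) -> list[ProteinRecord]:
    """Keep records strictly longer than ``min_aa`` residues."""
    return [r for r in records if len(r) > min_aa]


def build_network(
    records: Sequence[ProteinRecord],
    hits: Iterable[AlignmentHit],
    threshold: float = 1e-30,
) -> nx.Graph:
    """Build the SSN from records and pairwise hits at an E-value cutoff.

    Reciprocal hits (a,b) and (b,a) collapse to one edge carrying the minimum
    E-value and maximum bitscore observed. Hits above the threshold are
    discarded; hits naming unknown sequence ids raise ``ValueError``.
    """
    net = nx.Graph(threshold=threshold)
    for r in records:
        net.add_node(r.id, family=r.family, habitat=r.habitat)
    for h in hits:
        for sid in (h.query_id, h.subject_id):
            if sid not in net:
                raise ValueError(f"hit references unknown sequence id {sid!r}")
        if h.query_id == h.subject_id:
            continue
        if h.evalue > threshold:
            continue
        u, v = h.query_id, h.subject_id
        if net.has_edge(u, v):
            data = net.edges[u, v]
            data["evalue"] = min(data["evalue"], h.evalue)
            data["bitscore"] = max(data["bitscore"], h.bitscore)
        else:
            net.add_edge(u, v, evalue=h.evalue, bitscore=h.bitscore)
    return net


def connected_components(net: nx.Graph) -> list[set]:
    """Components as node sets, largest first (ties broken by smallest id)."""
    comps = [set(c) for c in nx.connected_components(net)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def isolated_nodes(net: nx.Graph) -> set:
    return {n for n, d in net.degree() if d == 0}


@dataclass
class GlobalTopology:
    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    n_components: int
    n_isolated: int
    avg_clustering: float
    char_path_length: float
    connected_pair_pct: float
    centralization: float


def _path_length_stats(net: nx.Graph) -> tuple[float, float]:
    """(characteristic path length over finite ordered pairs, % of ordered
    pairs with a finite path)."""
    n = net.number_of_nodes()
    if n < 2:
        return 0.0, 0.0
    total_dist = 0
    finite_pairs = 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        s = len(comp)
        if s < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total_dist += sum(dists.values())
            finite_pairs += s - 1
    cpl = total_dist / finite_pairs if finite_pairs else 0.0
    return cpl, 100.0 * finite_pairs / (n * (n - 1))


def global_topology(net: nx.Graph, *, detailed: bool = True) -> GlobalTopology:
    """Whole-network summary statistics.

    Clustering of degree<2 nodes counts as 0 and is included in the average;
    centralization is Freeman degree centralization; characteristic path
    length averages over ordered pairs with a finite path.

    ``detailed=False`` skips the clustering and shortest-path statistics
    (reported as NaN) — these cost O(N*K) and are rarely needed when only
    the degree/density summaries of a large network are of interest.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    k = net.number_of_edges()
    degrees = [d for _, d in net.degree()]
    avg_degree = 2.0 * k / n
    density = 2.0 * k / (n * (n - 1)) if n > 1 else 0.0
    comps = list(nx.connected_components(net))
    n_iso = len(isolated_nodes(net))
    if detailed:
        avg_clust = nx.average_clustering(net)
        cpl, pct = _path_length_stats(net)
    else:
        avg_clust = cpl = pct = math.nan
    if n > 2:
        kmax = max(degrees)
        centralization = sum(kmax - d for d in degrees) / ((n - 1) * (n - 2))
    else:
        centralization = 0.0
    return GlobalTopology(
        n_nodes=n,
        n_edges=k,
        avg_degree=avg_degree,
        density=density,
        n_components=len(comps),
        n_isolated=n_iso,
        avg_clustering=avg_clust,
        char_path_length=cpl,
        connected_pair_pct=pct,
        centralization=centralization,
    )


def node_metrics(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree, clustering coefficient, neighborhood connectivity
    (mean neighbor degree; 0 for isolated nodes) and closeness centrality
    (reachable count / sum of finite distances; 0 for isolated nodes)."""
    nodes = list(net.nodes)
    degree = dict(net.degree())
    clustering = nx.clustering(net)
    neigh = {
        n: (sum(degree[m] for m in net[n]) / degree[n] if degree[n] > 0 else 0.0)
        for n in nodes
    }
    closeness = nx.closeness_centrality(net, wf_improved=False)
    return pd.DataFrame(
        {
            "node": nodes,
            "degree": [degree[n] for n in nodes],
            "clustering": [clustering[n] for n in nodes],
            "neighborhood_connectivity": [neigh[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
        }
    ).set_index("node")


def greedy_cluster(
    records: Sequence[ProteinRecord],
    hits: Iterable[AlignmentHit],
    identity_threshold: float,
) -> dict[str, str]:
    """Greedy longest-first redundancy clustering on pairwise identities.

    Identity for a pair follows the CD-HIT convention: identical aligned
    positions divided by the length of the shorter sequence, so a short
    high-identity local match does not count as global redundancy. A sequence
    joins the first (longest-representative) cluster whose representative it
    matches at >= ``identity_threshold`` percent; otherwise it founds a new
    cluster. Returns member -> representative. This is an optional
    pre-network reduction, off by default in the pipeline.
    """
    if not 0 < identity_threshold <= 100:
        raise ValueError("identity_threshold must be in (0, 100]")
    length_of = {r.id: len(r) for r in records}
    ident: dict[tuple[str, str], float] = {}
    for h in hits:
        matches = h.pct_identity / 100.0 * h.aln_len
        shorter = min(
            length_of.get(h.query_id, h.aln_len), length_of.get(h.subject_id, h.aln_len)
        )
        pct = 100.0 * matches / shorter
        for key in ((h.query_id, h.subject_id), (h.subject_id, h.query_id)):
            ident[key] = max(ident.get(key, 0.0), pct)
    seq_of = {r.id: r.aa_seq for r in records}
    assignment: dict[str, str] = {}
    reps: list[str] = []
    for r in sorted(records, key=lambda r: (-len(r), r.id)):
        for rep in reps:
            # identical sequences always co-cluster even without a hit row
            if ident.get((r.id, rep), 0.0) >= identity_threshold or r.aa_seq == seq_of[rep]:
                assignment[r.id] = rep
                break
        else:
            reps.append(r.id)
            assignment[r.id] = r.id
    return assignment


def write_edges(net: nx.Graph, path: str | os.PathLike) -> None:
    """Edge list as TSV: id_a, id_b, evalue, bitscore (ids sorted per edge)."""
    rows = []
    for u, v, data in net.edges(data=True):
        a, b = sorted((u, v))
        rows.append((a, b, data.get("evalue", math.nan), data.get("bitscore", math.nan)))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tevalue\tbitscore\n")
        for a, b, ev, bs in rows:
            fh.write(f"{a}\t{b}\t{ev:.2e}\t{bs:.1f}\n")


def write_graphml(net: nx.Graph, path: str | os.PathLike) -> None:
    nx.write_graphml(net, os.fspath(path))
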