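"""Per-gene-family network attributes, divergence classification and curves.

Each gene family is analysed as the subgraph the SSN induces on its sequences.
The classification rule mirrors the qualitative reading of family networks:

* ``conserved``    — a single connected component with no isolated nodes
  (every sequence similar enough to hang together; e.g. dsrAB);
* ``diverged``     — at least half of the family's sequences are isolated
  nodes (the family has lost most within-family similarity);
* ``diversifying`` — everything in between (several components and/or a
  minority of isolated sequences).

"Core clusters" are the components containing sequences from every sampled
habitat; cross-habitat pairs inside them feed the dN/dS stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import connected_components, global_topology, isolated_nodes


@dataclass
class FamilyTopology:
    """One row of the per-family attribute table."""

    family: str
    n_nodes: int
    avg_degree: float
    n_components: int
    n_isolated: int
    clustering_coeff: float
    n_core_clusters: int
    f_components: float  # (n_components - 1) / max(n_nodes - 1, 1)
    f_isolated: float  # n_isolated / n_nodes
    classification: str


def family_subnetworks(net: nx.Graph) -> dict[str, nx.Graph]:
    """Induced subgraph per family (cross-family edges belong to neither).

    Every node must carry a ``family`` attribute; families partition the
    node set.
    """
    by_family: dict[str, list] = {}
    for n, data in net.nodes(data=True):
        fam = data.get("family")
        if fam is None:
            raise ValueError(f"node {n!r} has no family label")
        by_family.setdefault(fam, []).append(n)
    return {fam: net.subgraph(nodes).copy() for fam, nodes in sorted(by_family.items())}


def core_clusters(subgraph: nx.Graph, habitats: Sequence[str]) -> list[set]:
    """Components whose nodes span every habitat in ``habitats``."""
    required = set(habitats)
    cores = []
    for comp in connected_components(subgraph):
        present = {subgraph.nodes[n].get("habitat") for n in comp}
        if required <= present:
            cores.append(comp)
    return cores


def classify_family(
    attrs: FamilyTopology, *, isolated_fraction_threshold: float = 0.5
) -> str:
    if attrs.n_components == 1 and attrs.n_isolated == 0:
        return "conserved"
    if attrs.f_isolated >= isolated_fraction_threshold:
        return "diverged"
    return "diversifying"


def family_attributes(
    subgraph: nx.Graph,
    family: str,
    habitats: Sequence[str],
    *,
    isolated_fraction_threshold: float = 0.5,
) -> FamilyTopology:
    """Attribute row for one family subgraph (classification included)."""
    if subgraph.number_of_nodes() == 0:
        raise ValueError(f"family {family!r} has no nodes")
    topo = global_topology(subgraph)
    n = topo.n_nodes
    attrs = FamilyTopology(
        family=family,
        n_nodes=n,
        avg_degree=topo.avg_degree,
        n_components=topo.n_components,
        n_isolated=topo.n_isolated,
        clustering_coeff=topo.avg_clustering,
        n_core_clusters=len(core_clusters(subgraph, habitats)),
        f_components=(topo.n_components - 1) / max(n - 1, 1),
        f_isolated=topo.n_isolated / n,
        classification="",
    )
    attrs.classification = classify_family(
        attrs, isolated_fraction_threshold=isolated_fraction_threshold
    )
    return attrs


def family_table(
    net: nx.Graph,
    habitats: Sequence[str],
    *,
    isolated_fraction_threshold: float = 0.5,
) -> pd.DataFrame:
    """Attribute table over all families in the network."""
    rows = [
        family_attributes(
            sub, fam, habitats, isolated_fraction_threshold=isolated_fraction_threshold
        ).__dict__
        for fam, sub in family_subnetworks(net).items()
    ]
    return pd.DataFrame(rows).set_index("family")


@dataclass
class PowerLawFit:
    """y = a * x**b fitted by least squares on log-log pairs."""

    prefactor: float
    exponent: float
    pearson_r: float
    r_squared: float
    n_points: int
    n_dropped: int


def fit_power_law(xs: Sequence[float], ys: Sequence[float]) -> PowerLawFit:
    """Fit y = a x^b by simple linear regression of ln y on ln x.

    Points with nonpositive x or y are dropped (and counted); fewer than 3
    usable points is an error. A zero-variance response reports slope 0 and
    r^2 = 0.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("xs and ys must have the same length")
    keep = (xs > 0) & (ys > 0)
    n_dropped = int((~keep).sum())
    lx, ly = np.log(xs[keep]), np.log(ys[keep])
    if lx.size < 3:
        raise ValueError(f"need >= 3 usable points, got {lx.size}")
    if np.allclose(ly, ly[0]) or np.allclose(lx, lx[0]):
        return PowerLawFit(
            prefactor=float(np.exp(ly.mean())),
            exponent=0.0,
            pearson_r=0.0,
            r_squared=0.0,
            n_points=int(lx.size),
            n_dropped=n_dropped,
        )
    res = stats.linregress(lx, ly)
    return PowerLawFit(
        prefactor=float(np.exp(res.intercept)),
        exponent=float(res.slope),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        n_points=int(lx.size),
        n_dropped=n_dropped,
    )


def topology_curves(metrics: pd.DataFrame) -> pd.DataFrame:
    """Bin node metrics by exact degree k >= 1.

    Input is the ``node_metrics`` table; output has one row per observed
    degree with the node count and the mean clustering, neighborhood
    connectivity and closeness at that degree.
    """
    pos = metrics[metrics["degree"] >= 1]
    grouped = pos.groupby("degree").agg(
        n_nodes=("degree", "size"),
        mean_clustering=("clustering", "mean"),
        mean_neighborhood_connectivity=("neighborhood_connectivity", "mean"),
        mean_closeness=("closeness", "mean"),
    )
    grouped.index.name = "degree"
    return grouped.sort_index()


def curve_power_laws(curves: pd.DataFrame) -> pd.DataFrame:
    """Power-law fits of each topology curve against degree."""
    rows = []
    for col in (
        "n_nodes",
        "mean_clustering",
        "mean_neighborhood_connectivity",
        "mean_closeness",
    ):
        try:
            fit = fit_power_law(curves.index.to_numpy(), curves[col].to_numpy())
            rows.append(
                {
                    "series": col,
                    "prefactor": fit.prefactor,
                    "exponent": fit.exponent,
                    "pearson_r": fit.pearson_r,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                }
            )
        except ValueError:
            rows.append(
                {
                    "series": col,
                    "prefactor": math.nan,
                    "exponent": math.nan,
                    "pearson_r": math.nan,
                    "r_squared": math.nan,
                    "n_points": int((curves[col] > 0).sum()),
                }
            )
    return pd.DataFrame(rows).set_index("series")


def shannon_index(abundances: Sequence[float]) -> float:
    """Shannon diversity H = -sum p ln p over nonzero proportions."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise ValueError("abundances sum to zero")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_transform(alpha: float) -> float:
    """Rarefaction-style transform of an alpha-diversity value.

    Implements the literal reading ``10 * log10(alpha) / ln(10)`` of an
    ambiguous printed formula; see docs/methods.md for why its output should
    not be compared against conventional Shannon indices.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    return 10.0 * math.log10(alpha) / math.log(10.0)
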