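"""Motif graphs and graph-theoretic characterisation of axo-axonic networks.

A motif graph restricts the connectome to edges from a chosen set of
presynaptic classes onto one postsynaptic class (descending neurons, for every
analysis here).  The metric bundle covers the quantities used to characterise
the DN→DN network: density under both the unordered-pair and ordered-pair
conventions, average shortest-path length (unweighted hops on the undirected
projection, largest connected component), average local clustering, seeded
Louvain communities and modularity, degree statistics, degree assortativity,
normalized betweenness (weighted, with distance = 1/weight), and the rich-club
curve Φ(k) = density of the subgraph induced by nodes of total degree ≥ k.

The random-graph baseline ⟨L⟩ = ln(n)/ln(m/n) gives the Erdős–Rényi
expectation of the average shortest-path length for the same node and edge
counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .connectome import ConnectomeTable, NeuronClass, Transmitter

__all__ = [
    "MotifGraph",
    "GraphMetrics",
    "RichClubCurve",
    "InputSummary",
    "build_motif_graph",
    "graph_metrics",
    "expected_random_path",
    "rich_club",
    "input_summary",
    "nt_composition",
    "laterality",
    "degree_histograms",
]

#: Sentinel for metrics undefined on degenerate graphs (single node, no pairs).
UNDEFINED = float("nan")


@dataclass
class MotifGraph:
    """A directed, weighted motif-restricted graph with node metadata."""

    graph: nx.DiGraph
    pre_classes: frozenset[NeuronClass]
    post_class: NeuronClass

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class GraphMetrics:
    n_nodes: int
    n_edges: int
    density_undirected_pairs: float
    density_ordered_pairs: float
    avg_shortest_path: float
    clustering_coefficient: float
    n_communities: int
    modularity: float
    degree_min: int
    degree_max: int
    degree_mean: float
    assortativity: float
    max_betweenness: float
    expected_random_path: float
    conventions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RichClubCurve:
    thresholds: list[int]
    phi: list[float]
    peak_k: int
    peak_phi: float


@dataclass
class InputSummary:
    """Per-DN axo-axonic input tallies and their population-level coupling."""

    per_dn: pd.DataFrame  # columns: neuron_id, partner_count, total_strength
    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float
    r_squared: float


def build_motif_graph(
    table: ConnectomeTable,
    pre_classes: Iterable[NeuronClass],
    post_class: NeuronClass = NeuronClass.DN,
) -> MotifGraph:
    """Restrict the connectome to pre∈pre_classes → post_class edges.

    Only connection-bearing neurons appear as nodes; neurons isolated under the
    motif restriction are excluded.
    """
    pre_set = frozenset(pre_classes)
    by_id = table.neuron_by_id()
    g = nx.DiGraph()
    for c in table.connections:
        pre = by_id[c.pre_id]
        post = by_id[c.post_id]
        if pre.neuron_class in pre_set and post.neuron_class is post_class:
            g.add_edge(c.pre_id, c.post_id, weight=c.weight)
    for nid in g.nodes:
        n = by_id[nid]
        g.nodes[nid].update(
            neuron_class=n.neuron_class.value,
            type_label=n.type_label,
            transmitter=n.transmitter.value,
            side=n.side,
        )
    return MotifGraph(graph=g, pre_classes=pre_set, post_class=post_class)


def expected_random_path(n: int, m: int) -> float:
    """Erdős–Rényi expectation ln(n)/ln(k̄) with k̄ = m/n.

    Defined only for mean degree above 1 (m > n); below that the log base
    collapses and the approximation is meaningless.
    """
    if n < 2:
        raise ValueError("need at least two nodes")
    if m <= n:
        raise ValueError(f"mean degree m/n = {m}/{n} must exceed 1")
    return math.log(n) / math.log(m / n)


def _undirected_lcc(g: nx.DiGraph) -> nx.Graph:
    u = g.to_undirected()
    if u.number_of_nodes() == 0:
        return u
    comp = max(nx.connected_components(u), key=len)
    return u.subgraph(comp).copy()


def graph_metrics(motif: MotifGraph | nx.DiGraph, louvain_seed: int = 0) -> GraphMetrics:
    """Compute the full metric bundle for a motif graph.

    Conventions (recorded in the result): path length and clustering are
    unweighted and taken on the undirected projection (paths on its largest
    connected component); modularity and betweenness use synaptic weights,
    betweenness treating distance as 1/weight; community detection is seeded
    Louvain at resolution 1.0 on the undirected projection.
    """
    g = motif.graph if isinstance(motif, MotifGraph) else motif
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        raise ValueError("empty graph")

    conventions = {
        "path": "unweighted hops, undirected projection, largest connected component",
        "clustering": "average local clustering, undirected projection, unweighted",
        "communities": f"Louvain, seed {louvain_seed}, resolution 1.0, weighted, undirected projection",
        "betweenness": "directed, weighted (distance = 1/weight), normalized",
        "assortativity": "total-degree assortativity on the undirected projection",
    }

    if n == 1:
        return GraphMetrics(
            n_nodes=1, n_edges=m,
            density_undirected_pairs=UNDEFINED, density_ordered_pairs=UNDEFINED,
            avg_shortest_path=UNDEFINED, clustering_coefficient=UNDEFINED,
            n_communities=1, modularity=UNDEFINED,
            degree_min=int(min(d for _, d in g.degree())), degree_max=int(max(d for _, d in g.degree())),
            degree_mean=2 * m / n, assortativity=UNDEFINED, max_betweenness=UNDEFINED,
            expected_random_path=UNDEFINED, conventions=conventions,
        )

    und = g.to_undirected()
    lcc = _undirected_lcc(g)
    if lcc.number_of_nodes() > 1:
        avg_path = nx.average_shortest_path_length(lcc)
    else:
        avg_path = UNDEFINED
    clustering = nx.average_clustering(und)

    communities = nx.community.louvain_communities(und, weight="weight", seed=louvain_seed)
    modularity = (
        nx.community.modularity(und, communities, weight="weight")
        if m > 0 else UNDEFINED
    )

    degrees = [d for _, d in g.degree()]
    bc: dict = {}
    if m:
        # distance attribute for weighted betweenness
        nx.set_edge_attributes(
            g, {(u, v): 1.0 / d.get("weight", 1) for u, v, d in g.edges(data=True)}, "invweight"
        )
        bc = nx.betweenness_centrality(g, weight="invweight", normalized=True)

    try:
        # degenerate degree distributions yield 0/0 inside networkx; report NaN
        with np.errstate(invalid="ignore", divide="ignore"):
            assort = nx.degree_assortativity_coefficient(und)
    except (ValueError, ZeroDivisionError):
        assort = UNDEFINED

    try:
        erp = expected_random_path(n, m)
    except ValueError:
        erp = UNDEFINED

    return GraphMetrics(
        n_nodes=n,
        n_edges=m,
        density_undirected_pairs=m / (n * (n - 1) / 2),
        density_ordered_pairs=m / (n * (n - 1)),
        avg_shortest_path=avg_path,
        clustering_coefficient=clustering,
        n_communities=len(communities),
        modularity=modularity,
        degree_min=int(min(degrees)),
        degree_max=int(max(degrees)),
        degree_mean=2 * m / n,
        assortativity=float(assort) if assort == assort else UNDEFINED,
        max_betweenness=max(bc.values()) if bc else UNDEFINED,
        expected_random_path=erp,
        conventions=conventions,
    )


def rich_club(motif: MotifGraph | nx.DiGraph) -> RichClubCurve:
    """Rich-club curve: Φ(k) = directed density of the total-degree ≥ k subgraph.

    Unnormalized (no degree-preserving null): Φ = 1 means the high-degree
    subgraph is fully connected.  Defined only where at least two nodes qualify.
    """
    g = motif.graph if isinstance(motif, MotifGraph) else motif
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degree = dict(g.degree())  # in + out
    ks: list[int] = []
    phis: list[float] = []
    for k in range(0, max(degree.values()) + 1):
        nodes = [v for v, d in degree.items() if d >= k]
        if len(nodes) < 2:
            break
        sub = g.subgraph(nodes)
        nk = len(nodes)
        ks.append(k)
        phis.append(sub.number_of_edges() / (nk * (nk - 1)))
    if not ks:
        return RichClubCurve([], [], -1, UNDEFINED)
    best = int(np.argmax(phis))
    return RichClubCurve(ks, phis, ks[best], phis[best])


def input_summary(
    table: ConnectomeTable,
    pre_classes: Iterable[NeuronClass] = (NeuronClass.DN, NeuronClass.AN, NeuronClass.IN),
) -> InputSummary:
    """Per-DN distinct-partner counts and total input strengths, with their
    population Pearson correlation and linear regression."""
    pre_set = frozenset(pre_classes)
    by_id = table.neuron_by_id()
    partners: dict[int, set[int]] = {}
    strength: dict[int, float] = {}
    for c in table.connections:
        if by_id[c.pre_id].neuron_class in pre_set and by_id[c.post_id].neuron_class is NeuronClass.DN:
            partners.setdefault(c.post_id, set()).add(c.pre_id)
            strength[c.post_id] = strength.get(c.post_id, 0.0) + c.weight
    rows = [
        (nid, len(partners[nid]), strength[nid]) for nid in sorted(partners)
    ]
    df = pd.DataFrame(rows, columns=["neuron_id", "partner_count", "total_strength"])
    if len(df) < 3 or df["partner_count"].nunique() < 2:
        return InputSummary(df, UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED)
    r, p = stats.pearsonr(df["partner_count"], df["total_strength"])
    fit = stats.linregress(df["partner_count"], df["total_strength"])
    return InputSummary(df, float(r), float(p), float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def nt_composition(motif: MotifGraph, grouping: str) -> dict[str, float]:
    """Connection-level transmitter fractions within a grouping.

    Groupings: ``homotypic`` (identical type label on both ends),
    ``heterotypic``, ``all``, or ``contralateral`` (endpoint sides L vs R).
    Fractions are over edges, keyed by the presynaptic transmitter, and sum
    to 1 when the grouping is nonempty.
    """
    g = motif.graph
    counts: dict[str, int] = {}
    total = 0
    for u, v in g.edges:
        same_type = g.nodes[u]["type_label"] == g.nodes[v]["type_label"]
        sides = (g.nodes[u]["side"], g.nodes[v]["side"])
        if grouping == "homotypic" and not same_type:
            continue
        if grouping == "heterotypic" and same_type:
            continue
        if grouping == "contralateral" and not (set(sides) == {"L", "R"}):
            continue
        t = g.nodes[u]["transmitter"]
        counts[t] = counts.get(t, 0) + 1
        total += 1
    return {t: c / total for t, c in sorted(counts.items())} if total else {}


def laterality(motif: MotifGraph) -> dict[str, float | int]:
    """Contralateral vs ipsilateral edge fractions.

    An edge is contralateral iff its endpoint sides are {L, R}; edges touching a
    midline/unknown side are excluded and counted separately.
    """
    g = motif.graph
    contra = ipsi = excluded = 0
    for u, v in g.edges:
        su, sv = g.nodes[u]["side"], g.nodes[v]["side"]
        if su in ("L", "R") and sv in ("L", "R"):
            if su != sv:
                contra += 1
            else:
                ipsi += 1
        else:
            excluded += 1
    classified = contra + ipsi
    return {
        "contralateral_fraction": contra / classified if classified else UNDEFINED,
        "ipsilateral_fraction": ipsi / classified if classified else UNDEFINED,
        "n_classified": classified,
        "n_excluded": excluded,
    }


def export_graphml(motif: MotifGraph, path) -> None:
    """Write the motif graph (node metadata + edge weights) as GraphML."""
    nx.write_graphml(motif.graph, path)


def export_adjacency_csv(motif: MotifGraph, path) -> None:
    """Weighted adjacency matrix as CSV: rows = presynaptic, cols = postsynaptic."""
    nodes = sorted(motif.graph.nodes)
    mat = nx.to_pandas_adjacency(motif.graph, nodelist=nodes, weight="weight", dtype=int)
    mat.to_csv(path)


def degree_histograms(motif: MotifGraph) -> dict[str, dict[int, int]]:
    """Integer-binned in- and out-degree histograms over nodes."""
    g = motif.graph
    out: dict[str, dict[int, int]] = {"in_degree": {}, "out_degree": {}}
    for _, d in g.in_degree():
        out["in_degree"][d] = out["in_degree"].get(d, 0) + 1
    for _, d in g.out_degree():
        out["out_degree"][d] = out["out_degree"].get(d, 0) + 1
    return out
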