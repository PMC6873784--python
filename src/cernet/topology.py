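"""Tripartite ceRNA network assembly, centrality panel, and subnetworks.

The network is undirected with typed nodes (lncRNA/miRNA/mRNA) and typed
edges (``lnc_mir``, ``mir_mrna``, optionally ``lnc_mrna`` co-expression
edges).  The metric panel per node is degree, unnormalized Brandes
betweenness, harmonic closeness divided by (n-1) (robust on disconnected
graphs), and PageRank with damping 0.85.  Hub ranking takes the top-k of
each dimension and reports the nodes common to all four lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .containers import FEATURE_CLASSES, ValidationError
from .triplets import CeRNATriplet

_RELATION_BY_CLASSES = {
    frozenset({"lncRNA", "miRNA"}): "lnc_mir",
    frozenset({"miRNA", "mRNA"}): "mir_mrna",
    frozenset({"lncRNA", "mRNA"}): "lnc_mrna",
}

METRIC_NAMES = ("degree", "betweenness", "closeness", "pagerank")


class TripartiteNetwork:
    """Typed undirected graph over lncRNA, miRNA and mRNA nodes.

    Thin wrapper over a :class:`networkx.Graph` enforcing the tripartite
    contract: endpoints must exist, edge relations are determined by the
    endpoint classes, self-loops and same-class edges are rejected, and
    duplicate edges are idempotent.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction ----------------------------------------------------
    def add_node(self, node_id: str, node_class: str) -> None:
        if node_class not in FEATURE_CLASSES:
            raise ValidationError(
                f"node class must be one of {FEATURE_CLASSES}, got {node_class!r}"
            )
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing["class"] != node_class:
            raise ValidationError(
                f"node {node_id!r} already present with class "
                f"{existing['class']!r}, cannot relabel to {node_class!r}"
            )
        self.graph.add_node(node_id, **{"class": node_class})

    def add_edge(self, u: str, v: str) -> None:
        for n in (u, v):
            if n not in self.graph:
                raise ValidationError(f"edge endpoint {n!r} is not a node")
        if u == v:
            raise ValidationError(f"self-loop on {u!r} is not allowed")
        key = frozenset({self.node_class(u), self.node_class(v)})
        relation = _RELATION_BY_CLASSES.get(key)
        if relation is None:
            raise ValidationError(
                f"edge {u!r}-{v!r} joins two {self.node_class(u)!r} nodes"
            )
        self.graph.add_edge(u, v, relation=relation)

    # -- accessors -------------------------------------------------------
    def node_class(self, node_id: str) -> str:
        if node_id not in self.graph:
            raise ValidationError(f"unknown node {node_id!r}")
        return self.graph.nodes[node_id]["class"]

    def nodes(self, node_class: Optional[str] = None) -> list[str]:
        if node_class is None:
            return sorted(self.graph.nodes)
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["class"] == node_class
        )

    def edges(self, relation: Optional[str] = None) -> list[tuple[str, str, str]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            if relation is None or d["relation"] == relation:
                a, b = sorted((u, v))
                out.append((a, b, d["relation"]))
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in FEATURE_CLASSES}
        for _, d in self.graph.nodes(data=True):
            counts[d["class"]] += 1
        return counts

    def __eq__(self, other) -> bool:
        if not isinstance(other, TripartiteNetwork):
            return NotImplemented
        return (
            dict(self.graph.nodes(data="class"))
            == dict(other.graph.nodes(data="class"))
            and self.edges() == other.edges()
        )


@dataclass(frozen=True)
class NodeMetricsRecord:
    """The four-metric centrality panel for one node."""

    node_id: str
    node_class: str
    degree: int
    betweenness: float
    closeness: float
    pagerank: float


@dataclass(frozen=True)
class PairCountRecord:
    """First (lncRNA-miRNA) and secondary (miRNA-mRNA) pair counts."""

    lncrna_id: str
    n_first: int
    n_secondary: int

    @property
    def total(self) -> int:
        return self.n_first + self.n_secondary


def assemble_network(
    triplets: Iterable[CeRNATriplet],
    include_lnc_mrna_edges: bool = False,
) -> TripartiteNetwork:
    """Union of triplet members and their lnc_mir / mir_mrna edges.

    ``include_lnc_mrna_edges`` additionally adds the co-expression
    lncRNA-mRNA edge of every triplet.  Duplicate triplets are idempotent.
    """
    net = TripartiteNetwork()
    for t in triplets:
        net.add_node(t.lncrna_id, "lncRNA")
        net.add_node(t.mirna_id, "miRNA")
        net.add_node(t.mrna_id, "mRNA")
        net.add_edge(t.lncrna_id, t.mirna_id)
        net.add_edge(t.mirna_id, t.mrna_id)
        if include_lnc_mrna_edges:
            net.add_edge(t.lncrna_id, t.mrna_id)
    return net


def node_metrics(network: TripartiteNetwork) -> list[NodeMetricsRecord]:
    """Degree, betweenness, harmonic closeness and PageRank per node.

    Betweenness is the unnormalized Brandes count on the undirected graph
    (each unordered pair counted once); closeness is harmonic centrality
    divided by (n-1), so unreachable nodes contribute 0; PageRank uses
    damping 0.85 with a uniform teleport vector, converged to L1 < 1e-12.
    """
    g = network.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValidationError("cannot compute metrics on an empty network")
    betweenness = nx.betweenness_centrality(g, normalized=False)
    harmonic = nx.harmonic_centrality(g)
    if n > 1:
        pagerank = nx.pagerank(g, alpha=0.85, tol=1e-12 / n, max_iter=10_000)
    else:
        pagerank = {next(iter(g.nodes)): 1.0}
    records = []
    for node in sorted(g.nodes):
        records.append(
            NodeMetricsRecord(
                node_id=node,
                node_class=g.nodes[node]["class"],
                degree=int(g.degree(node)),
                betweenness=float(betweenness[node]),
                closeness=float(harmonic[node] / (n - 1)) if n > 1 else 0.0,
                pagerank=float(pagerank[node]),
            )
        )
    return records


def rank_top(
    metrics: Sequence[NodeMetricsRecord],
    k: int = 20,
    class_filter: Optional[str] = None,
) -> dict:
    """Top-k of each metric dimension plus the all-dimension intersection.

    Each list is sorted descending with ties broken lexicographically by
    node id.  The intersection report lists nodes (optionally restricted to
    one feature class) present in all four top-k lists.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    tops: dict[str, list[str]] = {}
    for name in METRIC_NAMES:
        ranked = sorted(metrics, key=lambda m: (-getattr(m, name), m.node_id))
        tops[name] = [m.node_id for m in ranked[:k]]
    common = set(tops[METRIC_NAMES[0]])
    for name in METRIC_NAMES[1:]:
        common &= set(tops[name])
    classes = {m.node_id: m.node_class for m in metrics}
    if class_filter is not None:
        common = {n for n in common if classes[n] == class_filter}
    return {"top": tops, "intersection": sorted(common)}


def count_pairs(network: TripartiteNetwork, lncrna_id: str) -> PairCountRecord:
    """First-relationship and secondary-relationship pair counts for a lncRNA.

    ``n_first`` counts the lncRNA's miRNA neighbors; ``n_secondary`` counts
    the distinct miRNA-mRNA edges incident to those miRNAs.
    """
    if network.node_class(lncrna_id) != "lncRNA":
        raise ValidationError(
            f"{lncrna_id!r} has class {network.node_class(lncrna_id)!r}, "
            "expected lncRNA"
        )
    g = network.graph
    mirnas = [
        m for m in g.neighbors(lncrna_id) if g.nodes[m]["class"] == "miRNA"
    ]
    secondary = {
        frozenset({m, v})
        for m in mirnas
        for v in g.neighbors(m)
        if g.nodes[v]["class"] == "mRNA"
    }
    return PairCountRecord(
        lncrna_id=lncrna_id, n_first=len(mirnas), n_secondary=len(secondary)
    )


def extract_subnetwork(
    network: TripartiteNetwork, lncrna_id: str
) -> TripartiteNetwork:
    """The lncRNA, its miRNA neighbors, their mRNA neighbors, and the
    lnc_mir / mir_mrna edges among them."""
    if lncrna_id not in network.graph:
        raise ValidationError(f"unknown node {lncrna_id!r}")
    if network.node_class(lncrna_id) != "lncRNA":
        raise ValidationError(f"{lncrna_id!r} is not a lncRNA node")
    g = network.graph
    mirnas = [
        m for m in g.neighbors(lncrna_id) if g.nodes[m]["class"] == "miRNA"
    ]
    mrnas = {
        v for m in mirnas for v in g.neighbors(m) if g.nodes[v]["class"] == "mRNA"
    }
    sub = TripartiteNetwork()
    sub.add_node(lncrna_id, "lncRNA")
    for m in mirnas:
        sub.add_node(m, "miRNA")
        sub.add_edge(lncrna_id, m)
    for v in sorted(mrnas):
        sub.add_node(v, "mRNA")
    for m in mirnas:
        for v in g.neighbors(m):
            if v in mrnas:
                sub.add_edge(m, v)
    return sub


def metrics_table(metrics: Sequence[NodeMetricsRecord]) -> pd.DataFrame:
    """Metric panel table (betweenness, closeness, degree, pagerank, name, type)."""
    return pd.DataFrame(
        {
            "betweenness": [m.betweenness for m in metrics],
            "closeness": [m.closeness for m in metrics],
            "degree": [m.degree for m in metrics],
            "pagerank": [m.pagerank for m in metrics],
            "name": [m.node_id for m in metrics],
            "type": [m.node_class for m in metrics],
        }
    )
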