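"""Centrality analysis and hub/bottleneck classification.

Hubs are the top fraction of nodes by degree centrality, bottlenecks the top
fraction by shortest-path betweenness; nodes in both sets are
bottleneck-hubs.  The graph is treated as undirected and unweighted and both
edge types (co-expression and interaction) count.  Betweenness uses raw
(unnormalized) counts with fractional credit for tied shortest paths and
endpoints excluded; within disconnected graphs, unreachable pairs contribute
nothing.  Only ranks matter for the top-fraction rule, so normalization
conventions do not affect classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import igraph as ig
import pandas as pd

from .errors import ValidationError
from .network import Network


def _betweenness(net: Network, nodes: list[str]) -> list[float]:
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.graph.edges()]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    return [float(b) for b in g.betweenness(directed=False)]


def centralities(net: Network) -> pd.DataFrame:
    """Per-node degree centrality and betweenness with competition ranks.

    Degree centrality is degree/(n-1) with a single global n (the full node
    count, not per-component).  Ranks are 1 = most central; ties share the
    better rank.
    """
    if net.n_nodes == 0:
        raise ValidationError("empty network")
    nodes = net.nodes()
    n = len(nodes)
    degree = [net.graph.degree(v) for v in nodes]
    dc = [d / (n - 1) if n > 1 else 0.0 for d in degree]
    btw = _betweenness(net, nodes) if n > 1 else [0.0]
    table = pd.DataFrame(
        {
            "protein_id": [net.protein_of(v) for v in nodes],
            "degree": degree,
            "degree_centrality": dc,
            "betweenness": btw,
        },
        index=pd.Index(nodes, name="node_id"),
    )
    table["rank_degree"] = (
        table["degree_centrality"].rank(ascending=False, method="min").astype(int))
    table["rank_betweenness"] = (
        table["betweenness"].rank(ascending=False, method="min").astype(int))
    return table


@dataclass
class TopologyClassification:
    hubs: set[str] = field(default_factory=set)
    bottlenecks: set[str] = field(default_factory=set)

    @property
    def bottleneck_hubs(self) -> set[str]:
        return self.hubs & self.bottlenecks


def _top_k(table: pd.DataFrame, k: int, primary: str, secondary: str) -> set[str]:
    order = sorted(
        table.index,
        key=lambda v: (-table.at[v, primary], -table.at[v, secondary], v))
    return set(order[:k])


def classify(table: pd.DataFrame, fraction: float = 0.2) -> TopologyClassification:
    """Top-fraction classification with k = ceil(fraction * n).

    Boundary ties are broken by the other centrality (higher wins), then by
    lexicographic node id, so both sets have exactly k members.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must be in (0, 1)")
    n = len(table)
    if n == 0:
        return TopologyClassification()
    k = math.ceil(fraction * n)
    return TopologyClassification(
        hubs=_top_k(table, k, "degree_centrality", "betweenness"),
        bottlenecks=_top_k(table, k, "betweenness", "degree_centrality"),
    )


@dataclass
class ProteinClassification:
    """Protein-level rollup: a protein is a hub/bottleneck if any of its
    peptide nodes is (the any-peptide rule)."""

    hub_proteins: set[str]
    bottleneck_proteins: set[str]

    @property
    def bottleneck_hub_proteins(self) -> set[str]:
        return self.hub_proteins & self.bottleneck_proteins

    @property
    def counts(self) -> dict[str, int]:
        return {
            "hubs": len(self.hub_proteins),
            "bottlenecks": len(self.bottleneck_proteins),
            "bottleneck_hubs": len(self.bottleneck_hub_proteins),
            "union": len(self.hub_proteins | self.bottleneck_proteins),
        }


def protein_level_rollup(table: pd.DataFrame,
                         classification: TopologyClassification) -> ProteinClassification:
    protein = table["protein_id"]
    return ProteinClassification(
        hub_proteins={protein.at[v] for v in classification.hubs},
        bottleneck_proteins={protein.at[v] for v in classification.bottlenecks},
    )


def classification_table(table: pd.DataFrame,
                         classification: TopologyClassification) -> pd.DataFrame:
    """Centrality table augmented with is_hub / is_bottleneck flags (TSV-ready)."""
    out = table.copy()
    out["is_hub"] = out.index.isin(classification.hubs)
    out["is_bottleneck"] = out.index.isin(classification.bottlenecks)
    out["is_bottleneck_hub"] = out["is_hub"] & out["is_bottleneck"]
    return out
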