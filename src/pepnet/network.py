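"""Shared network container and serialization.

Nodes are peptides carrying their parent protein identifier; edges are typed
(``coexpression`` for correlation-derived links, ``interaction`` for links
imported from a protein–protein interaction map, or ``coexpression+interaction``
when both sources support the same pair).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import FormatError, ValidationError

EDGE_COEXPRESSION = "coexpression"
EDGE_INTERACTION = "interaction"
EDGE_BOTH = "coexpression+interaction"

_VALID_EDGE_TYPES = {EDGE_COEXPRESSION, EDGE_INTERACTION, EDGE_BOTH}


@dataclass
class Network:
    """Undirected peptide network with typed edges.

    Thin wrapper over :class:`networkx.Graph`; node attribute ``protein_id``
    records the peptide→protein mapping, edge attributes ``edge_type`` and
    ``weight`` record provenance and strength.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, protein_id: str, **attrs) -> None:
        self.graph.add_node(node_id, protein_id=protein_id, **attrs)

    def add_edge(self, u: str, v: str, edge_type: str, weight: float = 1.0) -> None:
        if u == v:
            raise ValidationError(f"self-edge not allowed: {u!r}")
        if edge_type not in _VALID_EDGE_TYPES:
            raise ValidationError(f"unknown edge_type {edge_type!r}")
        self.graph.add_edge(u, v, edge_type=edge_type, weight=float(weight))

    # -- inspection -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def protein_of(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["protein_id"]

    def proteins(self) -> set[str]:
        return {d["protein_id"] for _, d in self.graph.nodes(data=True)}

    def edge_type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, _, d in self.graph.edges(data=True):
            counts[d["edge_type"]] = counts.get(d["edge_type"], 0) + 1
        return counts

    def copy(self) -> "Network":
        return Network(self.graph.copy())

    def peptides_of_protein(self, protein_id: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["protein_id"] == protein_id
        )


def write_network(net: Network, path: str | os.PathLike, dialect: str = "graphml") -> None:
    """Serialize a network as GraphML or a tab-delimited edge list.

    GraphML keeps node attributes (protein_id, module, centralities, ...) and
    round-trips losslessly; the TSV dialect writes one row per edge with
    columns ``node_a, node_b, edge_type, weight`` (isolated nodes are not
    representable there).
    """
    if dialect == "graphml":
        g = nx.Graph()
        for n, d in net.graph.nodes(data=True):
            g.add_node(n, **{k: v for k, v in d.items() if v is not None})
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, **{k: v for k, v in d.items() if v is not None})
        nx.write_graphml(g, path)
    elif dialect == "edge-list-tsv":
        rows = [
            {"node_a": min(u, v), "node_b": max(u, v),
             "edge_type": d["edge_type"], "weight": d.get("weight", 1.0)}
            for u, v, d in net.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["node_a", "node_b", "edge_type", "weight"])
        df = df.sort_values(["node_a", "node_b"], kind="mergesort")
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown network dialect {dialect!r}")


def read_network(path: str | os.PathLike, dialect: str = "graphml") -> Network:
    """Inverse of :func:`write_network` (the TSV dialect drops isolated nodes)."""
    if dialect == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        for n, d in g.nodes(data=True):
            out.add_node(n, **d)
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, **d)
        return Network(out)
    if dialect == "edge-list-tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"node_a", "node_b", "edge_type", "weight"}
        if not required.issubset(df.columns):
            raise FormatError(f"edge-list TSV missing columns {required - set(df.columns)}")
        net = Network()
        for row in df.itertuples(index=False):
            for n in (row.node_a, row.node_b):
                if n not in net.graph:
                    net.graph.add_node(n, protein_id="")
            w = row.weight if not (isinstance(row.weight, float) and math.isnan(row.weight)) else 1.0
            net.add_edge(row.node_a, row.node_b, edge_type=row.edge_type, weight=w)
        return net
    raise ValidationError(f"unknown network dialect {dialect!r}")
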