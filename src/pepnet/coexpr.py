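"""Thresholded Pearson co-expression networks fused with PPI edges.

Workflow: pairwise-complete Pearson correlation over peptides, a strict
high-correlation threshold (r > 0.9 by default) to admit only highly credible
edges, then integration of known protein–protein interactions as additional
typed edges between peptides whose parent proteins are already observed in
the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_model import ProteinInteractionSet, RatioMatrix
from .network import EDGE_BOTH, EDGE_COEXPRESSION, EDGE_INTERACTION, Network

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric peptide × peptide Pearson matrix (NaN = not estimable)."""

    values: pd.DataFrame
    protein_of: pd.Series

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.shape[0] != arr.shape[1]:
            raise ValidationError("correlation matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-12, equal_nan=True):
            raise ValidationError("correlation matrix must be symmetric")
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValidationError("correlation entries outside [-1, 1]")

    @property
    def peptides(self) -> list[str]:
        return list(self.values.index)


def pearson_matrix(matrix: RatioMatrix, min_periods: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation between peptide profiles.

    Each pair is estimated over the samples where both peptides are present;
    pairs with fewer than ``min_periods`` shared samples or with zero
    variance on the shared support get a missing (NaN) coefficient and are
    excluded from any downstream thresholding.
    """
    if matrix.values.shape[0] < 2:
        raise ValidationError("need at least 2 peptides for a correlation matrix")
    if matrix.values.shape[1] < 3:
        raise ValidationError("need at least 3 samples for a correlation matrix")
    corr = matrix.values.T.corr(method="pearson", min_periods=min_periods)
    vals = corr.to_numpy()
    np.fill_diagonal(vals, 1.0)
    vals = np.clip(vals, -1.0, 1.0)
    corr = pd.DataFrame(vals, index=corr.index, columns=corr.columns)
    return CorrelationMatrix(values=corr, protein_of=matrix.protein_of.copy())


def threshold_network(corr: CorrelationMatrix, r_min: float = 0.9,
                      absolute: bool = False) -> Network:
    """Connect peptide pairs whose correlation strictly exceeds ``r_min``.

    The default is the signed rule (r > r_min); ``absolute=True`` admits
    strong negative correlations as well (|r| > r_min).  Peptides without any
    edge are dropped from the network.
    """
    if not 0.0 < r_min < 1.0:
        raise ValidationError("r_min must be in (0, 1)")
    arr = corr.values.to_numpy()
    peptides = corr.peptides
    score = np.abs(arr) if absolute else arr
    iu, ju = np.triu_indices(len(peptides), k=1)
    keep = np.isfinite(score[iu, ju]) & (score[iu, ju] > r_min)
    net = Network()
    used = set()
    for i, j in zip(iu[keep], ju[keep]):
        used.add(i)
        used.add(j)
    for i in sorted(used):
        net.add_node(peptides[i], protein_id=str(corr.protein_of.iloc[i]))
    for i, j in zip(iu[keep], ju[keep]):
        net.add_edge(peptides[i], peptides[j], edge_type=EDGE_COEXPRESSION,
                     weight=float(arr[i, j]))
    logger.info("co-expression network: %d/%d peptides, %d edges (r > %.3g)",
                net.n_nodes, len(peptides), net.n_edges, r_min)
    return net


def integrate_ppi(net: Network, ppi: ProteinInteractionSet,
                  mode: str = "all-pairs") -> Network:
    """Overlay PPI edges onto the co-expression network.

    Only protein pairs with peptides already present in the network
    contribute (no new nodes).  ``all-pairs`` connects every peptide of one
    protein to every peptide of the other; ``representative`` connects only
    the highest-degree peptide of each protein (ties broken by lexicographic
    peptide id).  A pair already holding a co-expression edge is re-typed as
    carrying both kinds of evidence rather than duplicated.
    """
    if mode not in ("all-pairs", "representative"):
        raise ValidationError(f"unknown PPI integration mode {mode!r}")
    out = net.copy()
    by_protein: dict[str, list[str]] = {}
    for n, d in out.graph.nodes(data=True):
        by_protein.setdefault(d["protein_id"], []).append(n)

    def representative(protein: str) -> str:
        # degrees taken from the input network so the choice does not depend
        # on the order in which PPI pairs are processed
        peps = by_protein[protein]
        return min(peps, key=lambda p: (-net.graph.degree(p), p))

    n_added = n_retyped = 0
    for a, b in sorted(ppi.edges):
        if a not in by_protein or b not in by_protein:
            continue
        if mode == "representative":
            pairs = [(representative(a), representative(b))]
        else:
            pairs = [(u, v) for u in by_protein[a] for v in by_protein[b]]
        for u, v in pairs:
            if u == v:
                continue
            if out.graph.has_edge(u, v):
                d = out.graph[u][v]
                if d["edge_type"] == EDGE_COEXPRESSION:
                    d["edge_type"] = EDGE_BOTH
                    n_retyped += 1
            else:
                out.add_edge(u, v, edge_type=EDGE_INTERACTION)
                n_added += 1
    logger.info("PPI integration (%s): +%d interaction edges, %d co-expression "
                "edges also PPI-supported", mode, n_added, n_retyped)
    return out
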