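"""Weighted co-expression module detection and module–trait analysis.

The chain follows the standard weighted-network recipe: a soft-threshold
power adjacency a_ij = |r_ij|^beta, the topological overlap similarity

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with l_ij the dot product of adjacency rows i and j and k_i the row sum
(connectivity), average-linkage hierarchical clustering of the dissimilarity
1 - TOM, an adaptive tree cut into modules with a minimum size, per-module
eigengenes (first principal component of the standardized member submatrix),
eigengene–trait Pearson correlation with a t-based p-value, trimming of weak
topological-overlap links, per-module hub/bottleneck peptides, and a minimum
spanning tree layout per module.

Modules are labeled by Roman ordinals in decreasing size order; peptides in
no module carry an explicit background label that is never treated as a
module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import topology
from .coexpr import CorrelationMatrix
from .errors import ValidationError
from .io_model import RatioMatrix, StudyDesign
from .network import EDGE_COEXPRESSION, Network
from .synthetic import BACKGROUND_LABEL, roman

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# adjacency and topological overlap
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyMatrix:
    """Soft-threshold connection strengths in [0, 1], zero diagonal."""

    values: pd.DataFrame
    protein_of: pd.Series
    power: int = 6
    signed: bool = False

    @property
    def connectivity(self) -> pd.Series:
        return self.values.sum(axis=1)


@dataclass
class TOMatrix:
    """Topological overlap similarity (unit diagonal by convention)."""

    values: pd.DataFrame
    protein_of: pd.Series
    connectivity: pd.Series

    @property
    def peptides(self) -> list[str]:
        return list(self.values.index)


def soft_adjacency(corr: CorrelationMatrix, power: int = 6,
                   signed: bool = False) -> AdjacencyMatrix:
    """a_ij = |r_ij|^power (unsigned) or ((1+r_ij)/2)^power (signed).

    Missing coefficients contribute zero strength; the diagonal is zeroed so
    self-terms never enter connectivity or shared-neighbor sums.
    """
    if power < 1:
        raise ValidationError("power must be >= 1")
    r = corr.values.to_numpy(dtype=float)
    r = np.where(np.isfinite(r), r, 0.0)
    a = ((1.0 + r) / 2.0) ** power if signed else np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    df = pd.DataFrame(a, index=corr.values.index, columns=corr.values.columns)
    return AdjacencyMatrix(values=df, protein_of=corr.protein_of.copy(),
                           power=power, signed=signed)


def pick_power(corr: CorrelationMatrix, candidates: tuple[int, ...] = tuple(range(1, 13)),
               target_r2: float = 0.8, n_bins: int = 10,
               signed: bool = False) -> int:
    """Smallest power whose scale-free-topology fit reaches ``target_r2``.

    The fit is the R² of a log-log regression of binned connectivity
    frequency against mean binned connectivity.  Falls back to the candidate
    maximizing R² when none reaches the target; degenerate (all-equal)
    connectivities return the smallest candidate with a warning.
    """
    if not candidates:
        raise ValidationError("candidate power list is empty")
    candidates = tuple(sorted(candidates))
    best_power, best_r2 = candidates[0], -np.inf
    for power in candidates:
        k = soft_adjacency(corr, power=power, signed=signed).connectivity.to_numpy()
        if np.allclose(k, k[0]):
            warnings.warn("degenerate connectivity (all equal); "
                          "returning smallest candidate power", stacklevel=2)
            return candidates[0]
        r2 = _scale_free_r2(k, n_bins=n_bins)
        logger.info("power %d: scale-free fit R^2 = %.3f", power, r2)
        if r2 >= target_r2:
            return power
        if r2 > best_r2:
            best_power, best_r2 = power, r2
    logger.info("no candidate reached R^2 >= %.2f; using power %d (R^2 = %.3f)",
                target_r2, best_power, best_r2)
    return best_power


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(k[sel].mean())
        ys.append(sel.sum())
    if len(xs) < 3:
        return 0.0
    lx, ly = np.log10(xs), np.log10(ys)
    if np.std(lx) == 0 or np.std(ly) == 0:
        return 0.0
    return float(np.corrcoef(lx, ly)[0, 1] ** 2)


def topological_overlap(adj: AdjacencyMatrix) -> TOMatrix:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii := 1."""
    a = adj.values.to_numpy(dtype=float)
    k = a.sum(axis=1)
    l = a @ a  # zero diagonal makes self-terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / denom
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    df = pd.DataFrame(tom, index=adj.values.index, columns=adj.values.columns)
    return TOMatrix(values=df, protein_of=adj.protein_of.copy(),
                    connectivity=pd.Series(k, index=adj.values.index))


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    """peptide → module label (Roman ordinals, decreasing size) + background."""

    labels: pd.Series
    min_module_size: int
    background_label: str = BACKGROUND_LABEL

    def modules(self) -> list[str]:
        found = set(self.labels) - {self.background_label}
        return sorted(found, key=_roman_key)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> dict[str, int]:
        return {m: len(self.members(m)) for m in self.modules()}

    @property
    def n_background(self) -> int:
        return int((self.labels == self.background_label).sum())


_ROMAN_VALUES = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}


def _roman_key(label: str) -> int:
    total, prev = 0, 0
    for ch in reversed(label):
        val = _ROMAN_VALUES.get(ch, 0)
        total += val if val >= prev else -val
        prev = max(prev, val)
    return total


def cluster_modules(tom: TOMatrix, min_size: int = 30, min_gap: float = 0.01
                    ) -> tuple[np.ndarray, ModulePartition]:
    """Average-linkage clustering of 1 - TOM with a branch-stability tree cut.

    Modules are dendrogram branches rather than clusters at a single global
    height: every subtree with at least ``min_size`` leaves is a candidate,
    scored by its *stability* — the dissimilarity gap between the height at
    which the subtree itself forms and the height at which it merges into
    its parent.  A long-stemmed branch is a well-separated group under
    average linkage.  Candidates are accepted greedily in decreasing
    stability (ties: larger subtree, then lexicographically smallest member)
    provided they are disjoint from already-accepted branches and their
    stability reaches ``min_gap``; everything else falls to the background
    label.  Deterministic given its inputs.

    Returns the scipy linkage matrix (for dendrogram rendering) and the
    partition.
    """
    peptides = tom.peptides
    n = len(peptides)
    if n < 2:
        raise ValidationError("need at least 2 peptides to cluster")
    d = 1.0 - tom.values.to_numpy(dtype=float)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")

    labels = pd.Series(BACKGROUND_LABEL, index=peptides, name="module")
    if min_size > n:
        warnings.warn("min_size exceeds peptide count; all peptides background",
                      stacklevel=2)
        return z, ModulePartition(labels=labels, min_module_size=min_size)

    # subtree bookkeeping: ids 0..n-1 are leaves, n+i is the cluster formed
    # by linkage row i
    height = np.concatenate([np.zeros(n), z[:, 2]])
    size = np.concatenate([np.ones(n, dtype=int), z[:, 3].astype(int)])
    parent_height = np.full(2 * n - 1, np.nan)
    leaf_sets: list[set[int] | None] = [{i} for i in range(n)] + [None] * (n - 1)
    for i in range(n - 1):
        a, b = int(z[i, 0]), int(z[i, 1])
        parent_height[a] = parent_height[b] = z[i, 2]
        leaf_sets[n + i] = leaf_sets[a] | leaf_sets[b]  # type: ignore[operator]

    candidates = []
    for node in range(2 * n - 1):
        if size[node] < min_size:
            continue
        stability = (parent_height[node] - height[node]
                     if np.isfinite(parent_height[node]) else 0.0)
        if stability < min_gap:
            continue
        leaves = leaf_sets[node]
        anchor = min(peptides[i] for i in leaves)
        candidates.append((-stability, -size[node], anchor, node))
    candidates.sort()

    assigned: set[int] = set()
    accepted: list[set[int]] = []
    for _, _, _, node in candidates:
        leaves = leaf_sets[node]
        if leaves & assigned:
            continue
        accepted.append(leaves)
        assigned |= leaves

    if not accepted:
        warnings.warn("no branch reaches min_size with a stable stem; "
                      "all peptides background", stacklevel=2)
        return z, ModulePartition(labels=labels, min_module_size=min_size)

    # decreasing size; ties by lexicographically smallest member
    accepted.sort(key=lambda s: (-len(s), min(peptides[i] for i in s)))
    for rank, leaves in enumerate(accepted, start=1):
        labels.iloc[sorted(leaves)] = roman(rank)
    part = ModulePartition(labels=labels, min_module_size=min_size)
    logger.info("detected %d modules (sizes %s), %d background peptides",
                len(accepted), list(part.sizes().values()), part.n_background)
    return z, part


# ---------------------------------------------------------------------------
# eigengenes and module–trait correlation
# ---------------------------------------------------------------------------

def module_eigengene(matrix: RatioMatrix, partition: ModulePartition,
                     module: str) -> pd.Series:
    """First principal component of the module's standardized submatrix.

    Member peptide profiles are restricted to complete rows, z-scored, and
    decomposed by SVD; the per-sample eigengene has unit Euclidean norm and
    is oriented so its mean correlation with member profiles is >= 0.
    """
    members = partition.members(module)
    if not members:
        raise ValidationError(f"unknown or empty module {module!r}")
    sub = matrix.values.loc[[m for m in members if m in matrix.values.index]]
    sub = sub.dropna(axis=0, how="any")
    if sub.shape[0] < 2:
        raise ValidationError(
            f"module {module!r} has fewer than 2 complete member profiles")
    arr = sub.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValidationError(f"module {module!r} submatrix is essentially constant")
    arr = arr[keep]
    z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, ddof=0, keepdims=True)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    member_corr = (z @ eig) / (np.linalg.norm(z, axis=1) * np.linalg.norm(eig))
    if member_corr.mean() < 0:
        eig = -eig
    return pd.Series(eig, index=sub.columns, name=module)


def eigengene_matrix(matrix: RatioMatrix, partition: ModulePartition) -> pd.DataFrame:
    """Module × sample eigengene profiles for every detected module."""
    rows = {}
    for module in partition.modules():
        try:
            rows[module] = module_eigengene(matrix, partition, module)
        except ValidationError as exc:
            logger.warning("skipping eigengene for module %s: %s", module, exc)
    if not rows:
        return pd.DataFrame(columns=matrix.samples)
    return pd.DataFrame(rows).T


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson coefficient via t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait(eig: pd.DataFrame, design: StudyDesign, r_min: float = 0.55,
                 p_max: float = 0.1, absolute: bool = False) -> pd.DataFrame:
    """Eigengene–trait Pearson correlations with selection flags.

    A module/trait pair is selected when r > r_min (signed, the default) or
    |r| > r_min (``absolute=True``) and p < p_max.  Zero-variance traits are
    reported as untestable.
    """
    samples = list(eig.columns)
    if len(samples) < 3:
        raise ValidationError("need at least 3 samples for module-trait correlation")
    rows = []
    for module in eig.index:
        e = eig.loc[module].to_numpy(dtype=float)
        for trait in design.traits.columns:
            tvec = design.trait_vector(trait, samples).to_numpy(dtype=float)
            if np.std(tvec) == 0 or np.std(e) == 0:
                rows.append({"module": module, "trait": trait, "r": np.nan,
                             "p": np.nan, "selected": False, "testable": False})
                continue
            r = float(np.corrcoef(e, tvec)[0, 1])
            p = correlation_pvalue(r, len(samples))
            score = abs(r) if absolute else r
            rows.append({"module": module, "trait": trait, "r": r, "p": p,
                         "selected": bool(score > r_min and p < p_max),
                         "testable": True})
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p",
                                       "selected", "testable"])


# ---------------------------------------------------------------------------
# module networks: trimming, hubs, minimum spanning tree
# ---------------------------------------------------------------------------

@dataclass
class TrimResult:
    network: Network
    n_nodes_before: int
    n_nodes_after: int


def trim_module(tom: TOMatrix, partition: ModulePartition, module: str,
                to_min: float = 0.1) -> TrimResult:
    """Module-induced network keeping edges with TOM >= to_min.

    Equality survives (the rule removes strengths *below* the threshold);
    peptides isolated after trimming are dropped.
    """
    members = sorted(partition.members(module))
    if not members:
        raise ValidationError(f"unknown or empty module {module!r}")
    sub = tom.values.loc[members, members].to_numpy(dtype=float)
    net = Network()
    kept_edges = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if sub[i, j] >= to_min:
                kept_edges.append((members[i], members[j], sub[i, j]))
    used = {u for u, _, _ in kept_edges} | {v for _, v, _ in kept_edges}
    for m in members:
        if m in used:
            net.add_node(m, protein_id=str(tom.protein_of.loc[m]), module=module)
    for u, v, w in kept_edges:
        net.add_edge(u, v, edge_type=EDGE_COEXPRESSION, weight=float(w))
    return TrimResult(network=net, n_nodes_before=len(members),
                      n_nodes_after=net.n_nodes)


@dataclass
class ModuleHubs:
    hubs: list[str]
    bottlenecks: list[str]
    top_hub: str | None
    truncated: bool = False  # module smaller than the requested k


def module_hubs(net: Network, k: int = 10) -> ModuleHubs:
    """Top-k degree (hub) and betweenness (bottleneck) peptides of a module
    network, plus the single greatest-connectivity hub."""
    if net.n_nodes == 0:
        return ModuleHubs(hubs=[], bottlenecks=[], top_hub=None, truncated=True)
    table = topology.centralities(net)
    hub_order = sorted(table.index, key=lambda v: (-table.at[v, "degree"],
                                                   -table.at[v, "betweenness"], v))
    btw_order = sorted(table.index, key=lambda v: (-table.at[v, "betweenness"],
                                                   -table.at[v, "degree"], v))
    truncated = net.n_nodes < k
    return ModuleHubs(hubs=hub_order[:k], bottlenecks=btw_order[:k],
                      top_hub=hub_order[0], truncated=truncated)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def module_mst(tom: TOMatrix, partition: ModulePartition,
               module: str) -> list[tuple[str, str, float]]:
    """Minimum spanning tree of the module's complete 1 - TOM graph.

    Kruskal with edges sorted by (dissimilarity, node pair), so ties resolve
    deterministically by lexicographic edge key.  Modules of size < 2 yield
    an empty tree.
    """
    members = sorted(partition.members(module))
    if len(members) < 2:
        return []
    sub = tom.values.loc[members, members].to_numpy(dtype=float)
    edges = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            edges.append((1.0 - sub[i, j], members[i], members[j]))
    edges.sort()
    uf = _UnionFind(members)
    tree = []
    for w, u, v in edges:
        if uf.union(u, v):
            tree.append((u, v, float(w)))
            if len(tree) == len(members) - 1:
                break
    return tree


# ---------------------------------------------------------------------------
# module membership vs trait significance
# ---------------------------------------------------------------------------

def membership_significance(matrix: RatioMatrix, eig: pd.DataFrame,
                            design: StudyDesign, partition: ModulePartition,
                            module: str, trait: str
                            ) -> tuple[pd.DataFrame, float]:
    """Per-member (module membership kME, peptide trait significance) pairs.

    kME is the Pearson correlation between a member peptide profile and the
    module eigengene; peptide significance is the absolute correlation with
    the trait indicator.  Also returns the cross-peptide Pearson correlation
    between the two quantities (high when the module genuinely tracks the
    trait).
    """
    if module not in eig.index:
        raise ValidationError(f"module {module!r} has no eigengene")
    samples = list(eig.columns)
    e = eig.loc[module].to_numpy(dtype=float)
    tvec = design.trait_vector(trait, samples).to_numpy(dtype=float)
    rows = []
    for pep in partition.members(module):
        if pep not in matrix.values.index:
            continue
        prof = matrix.values.loc[pep, samples].to_numpy(dtype=float)
        if np.isnan(prof).any() or np.std(prof) == 0:
            continue
        kme = float(np.corrcoef(prof, e)[0, 1])
        sig = abs(float(np.corrcoef(prof, tvec)[0, 1])) if np.std(tvec) > 0 else np.nan
        rows.append({"peptide": pep, "module_membership": kme,
                     "peptide_significance": sig})
    df = pd.DataFrame(rows, columns=["peptide", "module_membership",
                                     "peptide_significance"])
    if len(df) >= 3 and df["peptide_significance"].notna().all():
        cross = float(np.corrcoef(df["module_membership"],
                                  df["peptide_significance"])[0, 1])
    else:
        cross = float("nan")
    return df, cross
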