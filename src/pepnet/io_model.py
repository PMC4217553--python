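"""Input/output and normalization for peptide-level quantitative proteomics.

The pipeline consumes four tab-delimited inputs:

* a peptide quantification table (``peptide``, ``protein``, one column per
  sample) holding abundances or treated/control ratios;
* a study design (``sample_id, condition, time_point, replicate_id,
  replicate_kind, control_sample_id, trait:<name>...``);
* a two-column protein–protein interaction edge list;
* an annotation map (``protein_id, namespace, category_id, category_name``).

Normalization follows the study convention for iTRAQ-style multi-condition
designs: abundances are converted to treated/control ratios, log2 scaled
(one unit = a twofold change), optionally restricted to complete cases, and
technical replicates are averaged.  Missing values are carried as NaN — never
zero, which is a legitimate log2 ratio.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, ValidationError
from .network import Network, read_network, write_network  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

MISSING_MARKERS = ("", "NA", "NaN", "nan")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Sample annotations: condition, time point, replication, control pairing.

    ``frame`` is indexed by sample_id with columns condition, time_point,
    replicate_id, replicate_kind, control_sample_id (None for control or
    ratio-input samples).  ``traits`` holds numeric per-sample indicators.
    ``ratio_input`` flags tables that already contain treated/control ratios
    (no control columns to divide by); by convention a design with no control
    pairing at all is ratio input.
    """

    frame: pd.DataFrame
    traits: pd.DataFrame
    ratio_input: bool = False

    def __post_init__(self) -> None:
        required = {"condition", "time_point", "replicate_id", "replicate_kind",
                    "control_sample_id"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"design missing columns: {sorted(missing)}")
        if self.frame.index.duplicated().any():
            raise ValidationError("duplicate sample_id in design")
        controls = set(self.frame.index[self.frame["control_sample_id"].isna()])
        for sid, ctrl in self.frame["control_sample_id"].items():
            if pd.notna(ctrl) and ctrl not in self.frame.index:
                raise ValidationError(
                    f"sample {sid!r} names unknown control {ctrl!r}")
        if not self.ratio_input and not controls:
            # every sample is paired -> at least one referenced control must exist
            raise ValidationError("no control samples present in a non-ratio design")
        if not self.traits.empty:
            vals = self.traits.to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ValidationError("trait indicators must be finite")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def treated_samples(self) -> list[str]:
        if self.ratio_input:
            return list(self.frame.index)
        return list(self.frame.index[self.frame["control_sample_id"].notna()])

    def control_of(self, sample_id: str):
        ctrl = self.frame.loc[sample_id, "control_sample_id"]
        return None if pd.isna(ctrl) else ctrl

    def trait_vector(self, name: str, samples: list[str] | None = None) -> pd.Series:
        if name not in self.traits.columns:
            raise DesignError(f"unknown trait {name!r}")
        vec = self.traits[name]
        return vec.loc[samples] if samples is not None else vec

    def subset(self, samples: list[str]) -> "StudyDesign":
        return StudyDesign(
            frame=self.frame.loc[samples].copy(),
            traits=self.traits.loc[samples].copy(),
            ratio_input=self.ratio_input,
        )


@dataclass
class PeptideAbundanceTable:
    """Peptides × samples abundance (or ratio) matrix with peptide→protein map.

    ``values`` is indexed by peptide_id with one column per sample; missing
    observations are NaN.  Every peptide maps to exactly one protein.
    """

    values: pd.DataFrame
    protein_of: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate peptide_id rows: {list(dupes)[:5]}")
        if not self.protein_of.index.equals(self.values.index):
            raise ValidationError("protein_of index does not match peptide rows")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("negative abundance values")

    @property
    def peptides(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RatioMatrix:
    """Peptides × samples log2 treated/control ratios (NaN = missing)."""

    values: pd.DataFrame
    protein_of: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate peptide_id rows")
        if not self.protein_of.index.equals(self.values.index):
            raise ValidationError("protein_of index does not match peptide rows")

    @property
    def peptides(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class ProteinInteractionSet:
    """Deduplicated unordered protein pairs from an experimental PPI map."""

    edges: set[tuple[str, str]] = field(default_factory=set)
    source_label: str = ""

    def __post_init__(self) -> None:
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-pair {a!r}")
            norm.add((min(a, b), max(a, b)))
        self.edges = norm

    def __len__(self) -> int:
        return len(self.edges)

    def proteins(self) -> set[str]:
        return {p for e in self.edges for p in e}


@dataclass
class AnnotationMap:
    """protein → functional category records (COG letters, KEGG pathways)."""

    frame: pd.DataFrame  # columns: protein_id, namespace, category_id, category_name

    def __post_init__(self) -> None:
        required = {"protein_id", "namespace", "category_id", "category_name"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"annotation map missing columns: {sorted(missing)}")
        # a category_id must have a single name within a namespace
        names = self.frame.groupby(["namespace", "category_id"])["category_name"].nunique()
        if (names > 1).any():
            bad = names[names > 1].index.tolist()
            raise ValidationError(f"conflicting category names: {bad[:5]}")

    def namespaces(self) -> list[str]:
        return sorted(self.frame["namespace"].unique())

    def subset(self, namespace: str) -> pd.DataFrame:
        return self.frame[self.frame["namespace"] == namespace]

    def annotated_proteins(self, namespace: str) -> set[str]:
        return set(self.subset(namespace)["protein_id"])

    def categories(self, namespace: str) -> dict[str, set[str]]:
        """category_id → protein set for one namespace."""
        sub = self.subset(namespace)
        return {cid: set(g["protein_id"]) for cid, g in sub.groupby("category_id")}

    def category_name(self, namespace: str, category_id: str) -> str:
        sub = self.subset(namespace)
        hits = sub.loc[sub["category_id"] == category_id, "category_name"]
        return str(hits.iloc[0]) if len(hits) else ""


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def load_design(path: str | os.PathLike) -> StudyDesign:
    """Read a study-design TSV (trait columns are prefixed ``trait:``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError("design file missing 'sample_id' column")
    df = df.set_index("sample_id")
    trait_cols = [c for c in df.columns if c.startswith("trait:")]
    traits = df[trait_cols].replace("", np.nan).astype(float)
    traits.columns = [c.split(":", 1)[1] for c in trait_cols]
    frame = df.drop(columns=trait_cols)
    frame["control_sample_id"] = frame["control_sample_id"].mask(
        frame["control_sample_id"] == "")
    ratio_input = frame["control_sample_id"].isna().all()
    return StudyDesign(frame=frame, traits=traits, ratio_input=bool(ratio_input))


def load_peptide_table(path: str | os.PathLike, design: StudyDesign) -> PeptideAbundanceTable:
    """Read a tab-delimited peptide quantification table.

    The header must name ``peptide`` and ``protein`` plus one column per
    design sample; empty cells or ``NA`` mark missing observations.
    Duplicate peptide rows (including the same peptide mapped to two
    proteins) are rejected — peptide-level analysis assumes unambiguous
    peptide→protein assignment.
    """
    df = pd.read_csv(path, sep="\t", na_values=list(MISSING_MARKERS))
    for col in ("peptide", "protein"):
        if col not in df.columns:
            raise FormatError(f"peptide table missing required column {col!r}")
    missing_samples = [s for s in design.samples if s not in df.columns]
    if missing_samples:
        raise FormatError(f"peptide table missing sample columns: {missing_samples}")
    if df["peptide"].duplicated().any():
        dupes = df.loc[df["peptide"].duplicated(), "peptide"].unique()
        raise ValidationError(f"duplicate peptide rows: {list(dupes)[:5]}")
    df = df.set_index("peptide")
    values = df[design.samples].astype(float)
    return PeptideAbundanceTable(values=values, protein_of=df["protein"].astype(str))


def load_ppi(path: str | os.PathLike) -> ProteinInteractionSet:
    """Read a two-column TSV of protein pairs; dedup and drop self-pairs."""
    edges: set[tuple[str, str]] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(f"{path}: malformed PPI line {lineno}: {line!r}")
            a, b = parts[0].strip(), parts[1].strip()
            if lineno == 1 and {a.lower(), b.lower()} & {"protein_a", "protein_b", "node_a"}:
                continue  # optional header
            if a == b:
                n_self += 1
                continue
            edges.add((min(a, b), max(a, b)))
    if n_self:
        logger.info("dropped %d self-pairs from %s", n_self, path)
    return ProteinInteractionSet(edges=edges, source_label=str(path))


def load_annotations(path: str | os.PathLike) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationMap(frame=df)


# ---------------------------------------------------------------------------
# normalization operations
# ---------------------------------------------------------------------------

def to_log_ratios(table: PeptideAbundanceTable, design: StudyDesign) -> RatioMatrix:
    """Convert abundances to log2(treated/control); control columns are dropped.

    A cell is missing in the output if either member of the pair is missing.
    Non-positive treated or control abundances cannot be log-ratioed; they
    propagate as missing with a logged warning rather than aborting.
    """
    treated = design.treated_samples
    out = pd.DataFrame(index=table.values.index, columns=treated, dtype=float)
    n_nonpos = 0
    if design.ratio_input:
        for s in treated:
            col = table.values[s].to_numpy(dtype=float)
            bad = (col <= 0) & ~np.isnan(col)
            n_nonpos += int(bad.sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                res = np.log2(np.where(bad, np.nan, col))
            out[s] = res
    else:
        for s in treated:
            ctrl = design.control_of(s)
            t = table.values[s].to_numpy(dtype=float)
            c = table.values[ctrl].to_numpy(dtype=float)
            bad = ((c <= 0) & ~np.isnan(c)) | ((t <= 0) & ~np.isnan(t))
            n_nonpos += int(bad.sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                res = np.log2(np.where(bad, np.nan, t / c))
            out[s] = res
    if n_nonpos:
        logger.warning("%d cells with non-positive abundance set to missing", n_nonpos)
    return RatioMatrix(values=out, protein_of=table.protein_of.copy())


def filter_complete_cases(matrix: RatioMatrix) -> RatioMatrix:
    """Drop every peptide with any missing value (row order preserved)."""
    keep = matrix.values.notna().all(axis=1)
    if not keep.any():
        warnings.warn("complete-case filter removed every peptide", stacklevel=2)
    return RatioMatrix(
        values=matrix.values.loc[keep].copy(),
        protein_of=matrix.protein_of.loc[keep].copy(),
    )


def filter_condition_coverage(matrix: RatioMatrix, design: StudyDesign) -> RatioMatrix:
    """Keep peptides observed (non-missing) in at least one sample per condition.

    This is the looser 'identified in all conditions' core-set rule used for
    the network branch, as opposed to the strict per-cell complete-case rule
    used for ordination.
    """
    frame = design.frame.loc[[s for s in matrix.samples if s in design.frame.index]]
    keep = pd.Series(True, index=matrix.values.index)
    for _, group in frame.groupby("condition"):
        cols = [s for s in group.index if s in matrix.values.columns]
        if cols:
            keep &= matrix.values[cols].notna().any(axis=1)
    if not keep.any():
        warnings.warn("condition-coverage filter removed every peptide", stacklevel=2)
    return RatioMatrix(values=matrix.values.loc[keep].copy(),
                       protein_of=matrix.protein_of.loc[keep].copy())


def _replicate_groups(design: StudyDesign, kind: str) -> list[tuple[str, list[str]]]:
    frame = design.frame
    of_kind = frame[frame["replicate_kind"] == kind]
    if of_kind.empty:
        raise DesignError(f"no samples of replicate_kind {kind!r} in design")
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for sid, row in of_kind.iterrows():
        key = f"{row['condition']}_{row['time_point']}"
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(sid)
    return [(k, groups[k]) for k in order]


def average_replicates(matrix: RatioMatrix, design: StudyDesign,
                       kind: str = "technical") -> RatioMatrix:
    """Average replicate columns of the stated kind within (condition, time point).

    The mean is taken over non-missing members; a cell missing in every group
    member stays missing.  Samples of other replicate kinds pass through
    unchanged.  Use :func:`collapse_design` for the matching design view.
    """
    groups = _replicate_groups(design, kind)
    grouped_samples = {s for _, members in groups for s in members}
    cols: dict[str, pd.Series] = {}
    order: list[str] = []
    for s in matrix.samples:
        if s not in grouped_samples:
            cols[s] = matrix.values[s]
            order.append(s)
    for key, members in groups:
        present = [s for s in members if s in matrix.values.columns]
        if not present:
            raise DesignError(f"replicate group {key!r} has no sample columns")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            cols[key] = matrix.values[present].mean(axis=1, skipna=True)
        order.append(key)
    out = pd.DataFrame({k: cols[k] for k in order}, index=matrix.values.index)
    return RatioMatrix(values=out, protein_of=matrix.protein_of.copy())


def collapse_design(design: StudyDesign, kind: str = "technical") -> StudyDesign:
    """Design view matching :func:`average_replicates` column grouping."""
    groups = _replicate_groups(design, kind)
    grouped = {s for _, members in groups for s in members}
    rows, trait_rows, index = [], [], []
    for sid in design.frame.index:
        if sid not in grouped:
            rows.append(design.frame.loc[sid])
            trait_rows.append(design.traits.loc[sid])
            index.append(sid)
    for key, members in groups:
        first = design.frame.loc[members[0]].copy()
        first["replicate_id"] = "mean"
        first["replicate_kind"] = "averaged"
        first["control_sample_id"] = np.nan
        rows.append(first)
        trait_rows.append(design.traits.loc[members].mean(axis=0))
        index.append(key)
    frame = pd.DataFrame(rows, index=index)
    traits = pd.DataFrame(trait_rows, index=index)
    return StudyDesign(frame=frame, traits=traits, ratio_input=True)


# ---------------------------------------------------------------------------
# writers for pipeline artifacts
# ---------------------------------------------------------------------------

def write_ratio_matrix(matrix: RatioMatrix, path: str | os.PathLike) -> None:
    df = matrix.values.copy()
    df.insert(0, "protein", matrix.protein_of)
    df.index.name = "peptide"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_ratio_matrix(path: str | os.PathLike) -> RatioMatrix:
    df = pd.read_csv(path, sep="\t", na_values=list(MISSING_MARKERS)).set_index("peptide")
    return RatioMatrix(values=df.drop(columns=["protein"]).astype(float),
                       protein_of=df["protein"].astype(str))


def write_peptide_table(table: PeptideAbundanceTable, path: str | os.PathLike) -> None:
    df = table.values.copy()
    df.insert(0, "protein", table.protein_of)
    df.index.name = "peptide"
    df.to_csv(path, sep="\t", na_rep="NA")


def write_design(design: StudyDesign, path: str | os.PathLike) -> None:
    frame = design.frame.copy()
    for name in design.traits.columns:
        frame[f"trait:{name}"] = design.traits[name]
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", na_rep="")


def write_ppi(ppi: ProteinInteractionSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(ppi.edges):
            fh.write(f"{a}\t{b}\n")


def write_annotations(ann: AnnotationMap, path: str | os.PathLike) -> None:
    ann.frame.to_csv(path, sep="\t", index=False)
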