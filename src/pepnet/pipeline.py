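"""End-to-end orchestration of the network analysis workflow.

Stages: input loading (or synthetic generation) → ratio normalization →
co-expression network → PPI fusion → topology → weighted module detection
with trait correlation → ordination → enrichment.  Every stage writes its
artifacts under the output directory and records parameters, input hashes
and row/edge counts in a JSON manifest; identical config and seed produce
identical manifest counts.

Validation failures abort with the stage name; optional inputs that are
absent (e.g. no PPI file) cause the dependent additions to be skipped, not
fail, and the manifest flags the skip.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr, enrichment, io_model, ordination, synthetic, topology, wgcna
from .errors import PepnetError, ValidationError
from .network import write_network

logger = logging.getLogger(__name__)

STAGES = ("inputs", "normalize", "network", "topology", "modules",
          "ordinate", "enrich")


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run (YAML-backed)."""

    output_dir: str = "pepnet_out"
    seed: int = 0
    # input paths (all optional when a synthetic section is given)
    peptide_table: str | None = None
    design: str | None = None
    ppi: str | None = None
    annotations: str | None = None
    synthetic: dict | None = None
    # thresholds
    r_min: float = 0.9
    hub_fraction: float = 0.2
    module_r_min: float = 0.55
    module_p_max: float = 0.1
    to_min: float = 0.1
    # co-expression options
    coexpr_mode: str = "all-pairs"
    coexpr_absolute: bool = False
    average_technical: bool = True
    condition_coverage_filter: bool = True
    # wgcna options
    power: int | str = 6  # integer or "auto"
    min_module_size: int = 30
    signed: bool = False
    module_hub_k: int = 10
    # ordination options
    autoscale: bool = False
    n_components: int = 2
    group_trait: str = "biofuel"
    # enrichment
    fdr: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.r_min < 1:
            raise ValidationError("r_min must be in (0, 1)")
        if not 0 < self.hub_fraction < 1:
            raise ValidationError("hub_fraction must be in (0, 1)")
        if not 0 < self.module_r_min < 1:
            raise ValidationError("module_r_min must be in (0, 1)")
        if not 0 < self.module_p_max <= 1:
            raise ValidationError("module_p_max must be in (0, 1]")
        if self.to_min < 0:
            raise ValidationError("to_min must be non-negative")
        if self.power != "auto" and int(self.power) < 1:
            raise ValidationError("power must be a positive integer or 'auto'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _synthetic_spec(config: PipelineConfig) -> synthetic.SyntheticSpec:
    raw = dict(config.synthetic or {})
    raw.setdefault("seed", config.seed)
    if "peptides_per_protein" in raw:
        raw["peptides_per_protein"] = tuple(raw["peptides_per_protein"])
    if "trait_assignment" in raw and raw["trait_assignment"] is not None:
        raw["trait_assignment"] = tuple(tuple(t) for t in raw["trait_assignment"])
    return synthetic.SyntheticSpec(**raw)


def run(config: PipelineConfig, stages: set[str] | None = None) -> dict:
    """Execute the workflow and return the manifest (also written to disk).

    ``stages`` restricts execution to a prefix of the stage chain (upstream
    dependencies are always included).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    wanted = set(STAGES) if stages is None else set(stages)
    unknown = wanted - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    last = max(STAGES.index(s) for s in wanted)
    needed = set(STAGES[: last + 1])  # upstream dependencies always run
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {},
                      "warnings": []}
    try:
        _run_stages(config, needed, out, manifest)
        manifest["status"] = "ok"
    except PepnetError as exc:
        manifest["status"] = "failed"
        manifest["failure"] = {"stage": manifest.get("_current_stage", "?"),
                               "reason": str(exc)}
        _write_manifest(manifest, out)
        raise
    manifest.pop("_current_stage", None)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    manifest = {k: v for k, v in manifest.items() if not k.startswith("_")}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _run_stages(config: PipelineConfig, needed: set[str], out: Path,
                manifest: dict) -> None:
    # ---- inputs ---------------------------------------------------------
    manifest["_current_stage"] = "inputs"
    stage: dict = {"parameters": {"seed": config.seed}}
    if config.synthetic is not None:
        spec = _synthetic_spec(config)
        table, design, ppi, ann, truth = synthetic.generate(spec)
        inputs_dir = out / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        io_model.write_peptide_table(table, inputs_dir / "peptide_table.tsv")
        io_model.write_design(design, inputs_dir / "design.tsv")
        io_model.write_ppi(ppi, inputs_dir / "ppi.tsv")
        io_model.write_annotations(ann, inputs_dir / "annotations.tsv")
        truth.module_of_protein.rename_axis("protein_id").to_frame().to_csv(
            inputs_dir / "ground_truth_modules.tsv", sep="\t")
        stage["synthetic"] = True
        stage["input_hashes"] = {p.name: _sha256(p) for p in sorted(inputs_dir.glob("*.tsv"))}
    else:
        if not config.peptide_table or not config.design:
            raise ValidationError("peptide_table and design paths are required "
                                  "when no synthetic section is given")
        design = io_model.load_design(config.design)
        table = io_model.load_peptide_table(config.peptide_table, design)
        ppi = io_model.load_ppi(config.ppi) if config.ppi else None
        ann = io_model.load_annotations(config.annotations) if config.annotations else None
        stage["synthetic"] = False
        stage["input_hashes"] = {
            name: _sha256(Path(p)) for name, p in
            (("peptide_table", config.peptide_table), ("design", config.design),
             ("ppi", config.ppi), ("annotations", config.annotations)) if p}
    if ppi is not None and len(ppi) == 0:
        ppi = None
    stage["counts"] = {"peptides": len(table.peptides),
                       "proteins": int(table.protein_of.nunique()),
                       "samples": len(design.samples),
                       "ppi_edges": len(ppi) if ppi else 0}
    manifest["stages"]["inputs"] = stage
    if "normalize" not in needed:
        return

    # ---- normalize ------------------------------------------------------
    manifest["_current_stage"] = "normalize"
    ratios = io_model.to_log_ratios(table, design)
    if config.average_technical and \
            (design.frame["replicate_kind"] == "technical").any():
        net_matrix = io_model.average_replicates(ratios, design, kind="technical")
        net_design = io_model.collapse_design(design, kind="technical")
    else:
        net_matrix, net_design = ratios, design
    if config.condition_coverage_filter:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net_matrix = io_model.filter_condition_coverage(net_matrix, net_design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        complete = io_model.filter_complete_cases(net_matrix)
    io_model.write_ratio_matrix(net_matrix, out / "log2_ratios.tsv")
    io_model.write_ratio_matrix(complete, out / "log2_ratios_complete.tsv")
    manifest["stages"]["normalize"] = {
        "parameters": {"average_technical": config.average_technical,
                       "condition_coverage_filter": config.condition_coverage_filter},
        "counts": {"peptides": len(net_matrix.peptides),
                   "complete_case_peptides": len(complete.peptides),
                   "samples": len(net_matrix.samples)},
        "outputs": ["log2_ratios.tsv", "log2_ratios_complete.tsv"]}
    if "network" not in needed:
        return

    # ---- co-expression network + PPI fusion ----------------------------
    manifest["_current_stage"] = "network"
    corr = coexpr.pearson_matrix(net_matrix)
    net = coexpr.threshold_network(corr, r_min=config.r_min,
                                   absolute=config.coexpr_absolute)
    ppi_integrated = False
    if net.n_nodes == 0:
        manifest["warnings"].append(
            "empty co-expression network; topology and hub enrichment skipped")
    elif ppi is not None:
        net = coexpr.integrate_ppi(net, ppi, mode=config.coexpr_mode)
        ppi_integrated = True
    else:
        manifest["warnings"].append("no PPI input; network is co-expression only")
    write_network(net, out / "network.graphml", dialect="graphml")
    write_network(net, out / "network_edges.tsv", dialect="edge-list-tsv")
    manifest["stages"]["network"] = {
        "parameters": {"r_min": config.r_min, "absolute": config.coexpr_absolute,
                       "ppi_mode": config.coexpr_mode,
                       "ppi_integrated": ppi_integrated},
        "counts": {"nodes": net.n_nodes, "edges": net.n_edges,
                   **{f"edges_{k}": v for k, v in net.edge_type_counts().items()}},
        "outputs": ["network.graphml", "network_edges.tsv"]}
    if "topology" not in needed:
        return

    # ---- topology -------------------------------------------------------
    manifest["_current_stage"] = "topology"
    rollup = None
    if net.n_nodes > 0:
        cents = topology.centralities(net)
        cls = topology.classify(cents, fraction=config.hub_fraction)
        rollup = topology.protein_level_rollup(cents, cls)
        topology.classification_table(cents, cls).to_csv(
            out / "topology.tsv", sep="\t")
        manifest["stages"]["topology"] = {
            "parameters": {"hub_fraction": config.hub_fraction},
            "counts": {"nodes": len(cents), "hubs": len(cls.hubs),
                       "bottlenecks": len(cls.bottlenecks),
                       "bottleneck_hubs": len(cls.bottleneck_hubs),
                       **{f"protein_{k}": v for k, v in rollup.counts.items()}},
            "outputs": ["topology.tsv"]}
    else:
        manifest["stages"]["topology"] = {"skipped": "empty network"}
    if "modules" not in needed:
        return

    # ---- weighted module detection -------------------------------------
    manifest["_current_stage"] = "modules"
    if config.power == "auto":
        power = wgcna.pick_power(corr, signed=config.signed)
    else:
        power = int(config.power)
    adj = wgcna.soft_adjacency(corr, power=power, signed=config.signed)
    tom = wgcna.topological_overlap(adj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, partition = wgcna.cluster_modules(tom, min_size=config.min_module_size)
    eig = wgcna.eigengene_matrix(net_matrix, partition)
    trait_table = (wgcna.module_trait(eig, net_design, r_min=config.module_r_min,
                                      p_max=config.module_p_max)
                   if len(eig) else pd.DataFrame(
                       columns=["module", "trait", "r", "p", "selected", "testable"]))
    selected = sorted(trait_table.loc[trait_table["selected"], "module"].unique(),
                      key=wgcna._roman_key)

    assign = partition.labels.rename_axis("peptide").to_frame()
    assign.insert(0, "protein", tom.protein_of)
    assign.to_csv(out / "module_assignment.tsv", sep="\t")
    if len(eig):
        eig.rename_axis("module").to_csv(out / "module_eigengenes.tsv", sep="\t")
    trait_table.to_csv(out / "module_trait.tsv", sep="\t", index=False)

    modules_dir = out / "modules"
    modules_dir.mkdir(exist_ok=True)
    trim_counts = {}
    for module in selected:
        trim = wgcna.trim_module(tom, partition, module, to_min=config.to_min)
        trim_counts[module] = {"before": trim.n_nodes_before,
                               "after": trim.n_nodes_after}
        write_network(trim.network, modules_dir / f"module_{module}_trimmed.graphml")
        hubs = wgcna.module_hubs(trim.network, k=config.module_hub_k)
        with open(modules_dir / f"module_{module}_hubs.json", "w") as fh:
            json.dump({"hubs": hubs.hubs, "bottlenecks": hubs.bottlenecks,
                       "top_hub": hubs.top_hub, "truncated": hubs.truncated},
                      fh, indent=2)
        mst = wgcna.module_mst(tom, partition, module)
        pd.DataFrame(mst, columns=["node_a", "node_b", "dissimilarity"]).to_csv(
            modules_dir / f"module_{module}_mst.tsv", sep="\t", index=False)
        module_traits = trait_table[(trait_table["module"] == module)
                                    & trait_table["selected"]]
        for trait in module_traits["trait"]:
            df, cross = wgcna.membership_significance(
                net_matrix, eig, net_design, partition, module, trait)
            df.to_csv(modules_dir / f"module_{module}_{trait}_membership.tsv",
                      sep="\t", index=False)
    manifest["stages"]["modules"] = {
        "parameters": {"power": power, "signed": config.signed,
                       "min_module_size": config.min_module_size,
                       "module_r_min": config.module_r_min,
                       "module_p_max": config.module_p_max,
                       "to_min": config.to_min},
        "counts": {"modules": len(partition.modules()),
                   "background_peptides": partition.n_background,
                   "module_sizes": partition.sizes(),
                   "selected_modules": list(selected),
                   "trim": trim_counts},
        "outputs": ["module_assignment.tsv", "module_eigengenes.tsv",
                    "module_trait.tsv"]}
    if "ordinate" not in needed:
        return

    # ---- ordination -----------------------------------------------------
    manifest["_current_stage"] = "ordinate"
    if len(complete.peptides) >= 2:
        pca_res = ordination.pca(complete, n_components=config.n_components,
                                 autoscale=config.autoscale)
        pca_res.scores.rename_axis("sample").to_csv(out / "pca_scores.tsv", sep="\t")
        pca_res.loadings.rename_axis("peptide").to_csv(
            out / "pca_loadings.tsv", sep="\t")
        ord_counts = {"pca_components": pca_res.scores.shape[1],
                      "pca_explained": [round(float(v), 6)
                                        for v in pca_res.explained_variance]}
        if config.group_trait in net_design.traits.columns:
            grp = net_design.traits[config.group_trait]
            groups = grp.map(lambda v: f"class_{v:g}")
            if groups.nunique() == 2:
                pls = ordination.plsda(complete, groups,
                                       n_components=config.n_components,
                                       autoscale=config.autoscale)
                pls.scores.rename_axis("sample").to_csv(
                    out / "plsda_scores.tsv", sep="\t")
                ord_counts["plsda_components"] = pls.scores.shape[1]
        manifest["stages"]["ordinate"] = {
            "parameters": {"autoscale": config.autoscale,
                           "n_components": config.n_components,
                           "group_trait": config.group_trait},
            "counts": ord_counts,
            "outputs": ["pca_scores.tsv", "pca_loadings.tsv"]}
    else:
        manifest["stages"]["ordinate"] = {"skipped": "fewer than 2 complete-case peptides"}
    if "enrich" not in needed:
        return

    # ---- enrichment -----------------------------------------------------
    manifest["_current_stage"] = "enrich"
    if ann is None:
        manifest["stages"]["enrich"] = {"skipped": "no annotation input"}
        return
    enrich_dir = out / "enrichment"
    enrich_dir.mkdir(exist_ok=True)
    counts: dict = {}
    if rollup is not None:
        net_background = net.proteins()
        for name, proteins in (("hubs", rollup.hub_proteins),
                               ("bottlenecks", rollup.bottleneck_proteins),
                               ("bottleneck_hubs", rollup.bottleneck_hub_proteins)):
            for namespace in ann.namespaces():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    df = enrichment.enrich(proteins & net_background,
                                           net_background, ann, namespace,
                                           fdr=config.fdr)
                df.to_csv(enrich_dir / f"{name}_{namespace}.tsv", sep="\t",
                          index=False)
                counts[f"{name}_{namespace}"] = len(df)
    module_background = set(tom.protein_of)
    for namespace in ann.namespaces():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tables = enrichment.enrich_modules(
                partition.labels, selected, tom.protein_of, ann,
                module_background, namespace, fdr=config.fdr)
        for key, df in tables.items():
            df.to_csv(enrich_dir / f"module_{key}_{namespace}.tsv", sep="\t",
                      index=False)
            counts[f"module_{key}_{namespace}"] = len(df)
    manifest["stages"]["enrich"] = {
        "parameters": {"fdr": config.fdr},
        "counts": counts,
        "outputs": sorted(p.name for p in enrich_dir.glob("*.tsv"))}
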