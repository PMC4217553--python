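"""Synthetic multi-condition proteomics bundles with planted network structure.

The generator emulates an iTRAQ-style stress study: a handful of stress
conditions (biofuel and environmental classes), two harvest time points,
technical replicates, ~10^3 tryptic peptides nested in proteins, planted
co-expression modules whose latent profiles correlate with condition-class
traits, independent missingness, module-enriched protein–protein interaction
edges, and an annotation map with pathway categories concentrated in specific
modules.  Every downstream stage therefore has exact ground truth.

Generative model (all on the log2-ratio scale):

* module latent profile = target-correlation mixture of the standardized
  trait indicator and an exactly orthogonalized noise profile, so the sample
  correlation between latent and trait equals the requested signed effect;
  the latent is drawn per biological sample and tiled over technical
  replicates, then standardized to zero mean / unit variance;
* protein profile = module latent + N(0, protein_noise_sd^2) per sample
  (background proteins are pure N(0, 1) noise);
* peptide profile = protein profile + N(0, peptide_noise_sd^2);
* cells are masked missing independently at ``missing_rate``;
* PPI edges are Bernoulli draws at a within-module and a background rate.

The emitted abundance table holds ratios (2**log2), matching a design whose
samples carry no control pairing (controls implicit at ratio 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_model import (
    AnnotationMap,
    PeptideAbundanceTable,
    ProteinInteractionSet,
    StudyDesign,
)

BACKGROUND_LABEL = "background"

# canonical study conditions, interleaved so any prefix holds both classes
_CONDITIONS = ["ethanol", "salt", "butanol", "nitrogen_starvation", "hexane"]
_BIOFUEL = {"ethanol", "butanol", "hexane"}

_COG_LETTERS = [
    ("C", "Energy production and conversion"),
    ("E", "Amino acid transport and metabolism"),
    ("G", "Carbohydrate transport and metabolism"),
    ("I", "Lipid transport and metabolism"),
    ("J", "Translation, ribosomal structure and biogenesis"),
    ("K", "Transcription"),
    ("L", "Replication, recombination and repair"),
    ("M", "Cell wall/membrane/envelope biogenesis"),
    ("O", "Post-translational modification, protein turnover, chaperones"),
    ("P", "Inorganic ion transport and metabolism"),
]

_KEGG_PATHWAYS = [
    ("ko00196", "Photosynthesis - antenna proteins"),
    ("ko00710", "Carbon fixation in photosynthetic organisms"),
    ("ko00540", "Lipopolysaccharide biosynthesis"),
    ("ko00290", "Valine, leucine and isoleucine biosynthesis"),
]

# default module→(trait, signed latent/trait correlation target); cycled over
# modules.  Mirrors the study layout: mostly positive biofuel-linked modules,
# one negative, plus environmentally linked ones.
_DEFAULT_TRAIT_PATTERN = [
    ("biofuel", 0.8),
    ("biofuel", 0.7),
    ("biofuel", -0.8),
    ("biofuel", 0.75),
    ("salt", 0.8),
    ("nitrogen_starvation", 0.8),
    ("biofuel", 0.7),
    ("salt", -0.7),
]

_AA = "ACDEFGHILMNPQSTVWY"  # K/R reserved for the tryptic terminus


def roman(n: int) -> str:
    """Roman numeral for a positive integer (module labels)."""
    if n <= 0:
        raise ValueError("roman() needs a positive integer")
    pairs = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
             (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
             (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for val, sym in pairs:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-structure generator (defaults = study scale)."""

    n_modules: int = 8
    proteins_per_module: int = 12
    background_proteins: int = 100
    peptides_per_protein: tuple[int, int] = (1, 10)
    n_conditions: int = 5
    time_points: int = 2
    technical_replicates: int = 2
    trait_assignment: tuple[tuple[str, str, float], ...] | None = None
    peptide_noise_sd: float = 0.3
    protein_noise_sd: float = 0.3
    missing_rate: float = 0.05
    ppi_within_module_rate: float = 0.3
    ppi_background_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_modules", "proteins_per_module", "n_conditions",
                     "time_points", "technical_replicates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.background_proteins < 0:
            raise ValidationError("background_proteins must be non-negative")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValidationError("peptides_per_protein must be a (min<=max) range >=1")
        for name in ("missing_rate", "ppi_within_module_rate", "ppi_background_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be a probability")
        if self.ppi_within_module_rate < self.ppi_background_rate:
            raise ValidationError("within-module PPI rate must be >= background rate")
        for name in ("peptide_noise_sd", "protein_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 2 <= self.n_conditions <= len(_CONDITIONS):
            raise ValidationError(
                f"n_conditions must be in [2, {len(_CONDITIONS)}]")

    # -- derived layout ---------------------------------------------------
    @property
    def conditions(self) -> list[str]:
        return _CONDITIONS[: self.n_conditions]

    @property
    def n_samples(self) -> int:
        return self.n_conditions * self.time_points * self.technical_replicates

    @property
    def module_labels(self) -> list[str]:
        return [roman(i + 1) for i in range(self.n_modules)]

    def resolved_trait_assignment(self) -> dict[str, tuple[str, float]]:
        """module label → (trait name, signed correlation target)."""
        if self.trait_assignment is not None:
            out = {m: (t, float(e)) for m, t, e in self.trait_assignment}
        else:
            out = {}
            for i, label in enumerate(self.module_labels):
                trait, effect = _DEFAULT_TRAIT_PATTERN[i % len(_DEFAULT_TRAIT_PATTERN)]
                if trait not in ("biofuel",) and trait not in self.conditions:
                    trait, effect = "biofuel", 0.7  # condition absent at small n_conditions
                out[label] = (trait, effect)
        for m, (t, e) in out.items():
            if not -1.0 <= e <= 1.0:
                raise ValidationError(f"effect for module {m} outside [-1, 1]")
        return out


@dataclass
class GroundTruth:
    """Planted structure: protein→module labels, latent profiles, traits."""

    module_of_protein: pd.Series
    latent_profiles: pd.DataFrame  # modules × samples, zero mean / unit variance
    trait_values: pd.DataFrame  # samples × traits
    trait_assignment: dict[str, tuple[str, float]] = field(default_factory=dict)
    enriched_category_of_module: dict[str, str] = field(default_factory=dict)

    def module_of_peptide(self, protein_of: pd.Series) -> pd.Series:
        return protein_of.map(self.module_of_protein).rename("module")


def expected_module_signal(spec: SyntheticSpec) -> float:
    """Population within-module correlation between peptides of different proteins.

    Under the variance-component model (latent var 1, protein noise var
    sigma_p^2, peptide noise var sigma_e^2) two module peptides from different
    proteins share only the latent component, giving
    r = 1 / (1 + sigma_p^2 + sigma_e^2).
    """
    return 1.0 / (1.0 + spec.protein_noise_sd ** 2 + spec.peptide_noise_sd ** 2)


def _build_design(spec: SyntheticSpec) -> StudyDesign:
    rows, index = [], []
    for cond in spec.conditions:
        for t in range(spec.time_points):
            tp = f"{24 * (t + 1)}h"
            for r in range(spec.technical_replicates):
                sid = f"{cond}_{tp}_r{r + 1}"
                rows.append({"condition": cond, "time_point": tp,
                             "replicate_id": f"r{r + 1}",
                             "replicate_kind": "technical",
                             "control_sample_id": np.nan})
                index.append(sid)
    frame = pd.DataFrame(rows, index=index)
    traits = pd.DataFrame(index=index)
    traits["biofuel"] = [1.0 if c in _BIOFUEL else 0.0 for c in frame["condition"]]
    for cond in spec.conditions:
        traits[cond] = (frame["condition"] == cond).astype(float)
    return StudyDesign(frame=frame, traits=traits, ratio_input=True)


def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        raise ValidationError("cannot standardize a constant profile")
    return v / sd


class _LatentFactory:
    """Latent module profiles with controlled cross-correlation.

    Each latent is effect × standardized-trait + sqrt(1-effect²) × noise.
    Noise components are drawn orthogonal to the whole (centered) trait span
    and, while sample-space dimensions last, to each other, so two planted
    latents correlate exactly effect_i × effect_j × corr(trait_i, trait_j) —
    chance noise correlations never entangle modules.
    """

    def __init__(self, trait_matrix: np.ndarray, rng: np.random.Generator):
        self.rng = rng
        self.n = trait_matrix.shape[0]
        centered = trait_matrix - trait_matrix.mean(axis=0, keepdims=True)
        self.basis: list[np.ndarray] = []  # orthonormal, spans centered traits
        for col in centered.T:
            self._try_extend(col)
        self._n_trait_dims = len(self.basis)

    def _project_out(self, v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        for b in self.basis:
            v = v - (v @ b) * b
        return v

    def _try_extend(self, v: np.ndarray) -> None:
        r = self._project_out(v)
        norm = np.linalg.norm(r)
        if norm > 1e-10 * math.sqrt(self.n):
            self.basis.append(r / norm)

    def noise(self) -> np.ndarray:
        """Unit-variance noise orthogonal to traits and previous noises."""
        g = self.rng.standard_normal(self.n)
        r = self._project_out(g)
        norm = np.linalg.norm(r)
        if norm <= 1e-10 * math.sqrt(self.n):
            # sample space exhausted: restart mutual orthogonality, keeping
            # orthogonality to the trait span
            self.basis = self.basis[: self._n_trait_dims]
            r = self._project_out(g)
            norm = np.linalg.norm(r)
        self.basis.append(r / norm)
        return _standardize(r)


def _latent_profile(trait: np.ndarray, effect: float, factory: _LatentFactory,
                    tile: int) -> np.ndarray:
    """Profile over biological samples with exact sample correlation ``effect``
    to the trait indicator, tiled over technical replicates and standardized."""
    z = _standardize(trait)
    e = factory.noise()
    lat = effect * z + math.sqrt(max(0.0, 1.0 - effect ** 2)) * e
    lat = np.repeat(lat, tile)
    return _standardize(lat)


def _peptide_sequences(rng: np.random.Generator, n: int) -> list[str]:
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(7, 16))
        body = "".join(rng.choice(list(_AA), size=length))
        seq = body + str(rng.choice(["K", "R"]))
        if seq not in seen:
            seen.add(seq)
            seqs.append(seq)
    return seqs


def generate(spec: SyntheticSpec) -> tuple[PeptideAbundanceTable, StudyDesign,
                                           ProteinInteractionSet, AnnotationMap,
                                           GroundTruth]:
    """Draw a full synthetic bundle; byte-identical under a fixed seed.

    Independent pseudo-random streams are spawned per artifact (expression,
    missingness, PPI, annotation, peptide ids) so, e.g., changing the PPI
    rates never perturbs the expression values.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_expr, rng_miss, rng_ppi, rng_ann, rng_ids = (
        np.random.default_rng(s) for s in ss.spawn(5))

    design = _build_design(spec)
    samples = design.samples
    tile = spec.technical_replicates
    n_bio = len(samples) // tile

    assignment = spec.resolved_trait_assignment()

    # --- latent module profiles -----------------------------------------
    factory = _LatentFactory(design.traits.to_numpy()[::tile], rng_expr)
    latents: dict[str, np.ndarray] = {}
    for label in spec.module_labels:
        trait_name, effect = assignment[label]
        trait_bio = design.traits[trait_name].to_numpy()[::tile]
        if trait_bio.std() == 0:
            raise ValidationError(f"trait {trait_name!r} is constant in this design")
        latents[label] = _latent_profile(trait_bio, effect, factory, tile)
    assert len(samples) == n_bio * tile

    # --- proteins and peptides ------------------------------------------
    module_of_protein: dict[str, str] = {}
    proteins: list[str] = []
    idx = 0
    for label in spec.module_labels:
        for _ in range(spec.proteins_per_module):
            pid = f"sll{1000 + idx:04d}"
            module_of_protein[pid] = label
            proteins.append(pid)
            idx += 1
    for _ in range(spec.background_proteins):
        pid = f"sll{1000 + idx:04d}"
        module_of_protein[pid] = BACKGROUND_LABEL
        proteins.append(pid)
        idx += 1

    lo, hi = spec.peptides_per_protein
    n_peps = {pid: int(rng_expr.integers(lo, hi + 1)) for pid in proteins}
    total_peptides = sum(n_peps.values())
    sequences = _peptide_sequences(rng_ids, total_peptides)

    rows, pep_ids, pep_prot = [], [], []
    seq_iter = iter(sequences)
    n_s = len(samples)
    for pid in proteins:
        label = module_of_protein[pid]
        if label == BACKGROUND_LABEL:
            base = rng_expr.standard_normal(n_s)
        else:
            base = latents[label] + rng_expr.normal(0.0, spec.protein_noise_sd, n_s)
        for _ in range(n_peps[pid]):
            pep = next(seq_iter)
            val = base + rng_expr.normal(0.0, spec.peptide_noise_sd, n_s)
            rows.append(val)
            pep_ids.append(pep)
            pep_prot.append(pid)

    log2 = pd.DataFrame(np.vstack(rows), index=pep_ids, columns=samples)
    mask = rng_miss.random(log2.shape) < spec.missing_rate
    log2 = log2.mask(mask)
    ratios = np.power(2.0, log2)  # NaN preserved

    table = PeptideAbundanceTable(
        values=ratios, protein_of=pd.Series(pep_prot, index=pep_ids, name="protein"))

    # --- PPI edges -------------------------------------------------------
    edges: set[tuple[str, str]] = set()
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            same = (module_of_protein[a] == module_of_protein[b]
                    and module_of_protein[a] != BACKGROUND_LABEL)
            rate = spec.ppi_within_module_rate if same else spec.ppi_background_rate
            if rng_ppi.random() < rate:
                edges.add((a, b))
    ppi = ProteinInteractionSet(edges=edges, source_label="synthetic")

    # --- annotations ------------------------------------------------------
    # KEGG: a small family of pathway categories, each concentrated in one
    # module (membership 0.7 in-module, 0.01 elsewhere); kept sparse so raw-p
    # enrichment over the family stays calibrated under null queries.
    ann_rows = []
    n_planted = min(len(_KEGG_PATHWAYS), spec.n_modules)
    enriched_of_module: dict[str, str] = {}
    for k in range(n_planted):
        cid, cname = _KEGG_PATHWAYS[k]
        home = spec.module_labels[k]
        enriched_of_module[home] = cid
        for pid in proteins:
            p = 0.7 if module_of_protein[pid] == home else 0.01
            if rng_ann.random() < p:
                ann_rows.append({"protein_id": pid, "namespace": "KEGG",
                                 "category_id": cid, "category_name": cname})
    # COG: every protein carries exactly one letter, uniformly (null namespace)
    letters = rng_ann.integers(0, len(_COG_LETTERS), size=len(proteins))
    for pid, li in zip(proteins, letters):
        cid, cname = _COG_LETTERS[int(li)]
        ann_rows.append({"protein_id": pid, "namespace": "COG",
                         "category_id": cid, "category_name": cname})
    ann = AnnotationMap(frame=pd.DataFrame(
        ann_rows, columns=["protein_id", "namespace", "category_id", "category_name"]))

    truth = GroundTruth(
        module_of_protein=pd.Series(module_of_protein, name="module"),
        latent_profiles=pd.DataFrame(latents, index=samples).T,
        trait_values=design.traits.copy(),
        trait_assignment=assignment,
        enriched_category_of_module=enriched_of_module,
    )
    return table, design, ppi, ann, truth


def recovery_benchmark_spec(seed: int = 7) -> SyntheticSpec:
    """Compact planted-module benchmark: 4 modules × 10 proteins × 3 peptides,
    no background proteins, 20 samples, moderate noise."""
    return SyntheticSpec(
        n_modules=4,
        proteins_per_module=10,
        background_proteins=0,
        peptides_per_protein=(3, 3),
        n_conditions=5,
        time_points=2,
        technical_replicates=2,
        peptide_noise_sd=0.3,
        protein_noise_sd=0.3,
        seed=seed,
    )
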