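# Methods

This note documents the models, numerical choices and open design decisions
behind `pepnet`, and what the synthetic validation does and does not show.

## Data model and normalization

The unit of analysis is the peptide, keyed by sequence and mapped to exactly
one protein; peptides mapping to multiple proteins are rejected at load,
since unambiguous peptide→protein assignment is the premise of peptide-level
networks. Abundances are converted to treated/control ratios per the design's
control pairing and log2 scaled, so one unit is a twofold change. Missing
observations are NaN throughout — never zero, which is a legitimate log2
ratio. Cells whose treated or control abundance is non-positive cannot be
log-ratioed; they become missing with a logged warning rather than aborting,
matching the removal-not-imputation posture of the rest of the pipeline.

Two filtered views feed the two analysis branches:

* **ordination branch** — strict complete cases (a peptide with any missing
  value is dropped), then technical replicates averaged within
  (condition, time point);
* **network branch** — peptides observed in at least one sample of every
  condition (the "core set" rule), with pairwise-complete correlation
  handling the remaining scattered missingness. Whether replicates are
  averaged before correlation is a config switch, default on.

Replicate averaging groups columns by (condition, time point) among samples
of the stated replicate kind and takes the mean over non-missing members; a
cell missing in every member stays missing. `collapse_design` provides the
matching design view with averaged traits.

## Co-expression network and PPI fusion

Pearson correlation is estimated per peptide pair over the samples where
both are present; pairs with fewer than 3 shared samples or zero variance on
the shared support are not estimable and can never form an edge. The edge
rule is the strict signed threshold r > 0.9 — the network connects only
highly credible positive co-expression; an absolute-value mode (|r| > r_min)
exists for exploratory use. Peptides without any edge are dropped.

PPI edges are added only between peptides of proteins already observed in
the co-expression network ("no new nodes"). The default `all-pairs` mode
connects every peptide of one protein to every peptide of the other,
preserving the protein-level interaction statement at peptide resolution
without privileging a peptide; `representative` mode connects only the
highest-degree peptide of each protein (ties: lexicographic id) for sparser
graphs. A pair supported by both evidence types carries a combined edge type
rather than a parallel edge, so degrees are not double-counted.

## Topology

The integrated graph is undirected and unweighted, with both edge types
traversable. Degree centrality is degree/(n−1) with the full node count n
(one global normalization, not per component). Betweenness is raw
shortest-path betweenness with fractional credit for tied shortest paths,
endpoints excluded; unreachable pairs contribute nothing. Only ranks enter
the classification, so normalization conventions are immaterial. Hubs and
bottlenecks are the top k = ⌈fraction·n⌉ (default fraction 0.2) by degree
centrality and betweenness respectively; boundary ties break by the other
metric, then lexicographic node id, so the sets have exactly k members.
Ceiling keeps the sets non-empty on small networks. Protein-level rollup
uses the any-peptide rule: a protein is a hub (bottleneck) if at least one
of its peptides is.

Betweenness is computed with igraph's Brandes implementation for speed; unit
and validation tests check it against a brute-force enumeration of all
shortest paths, keeping the implementation and the oracle independent.

## Weighted module detection

* **Adjacency**: a_ij = |r_ij|^β, unsigned by default (a signed variant
  ((1+r)/2)^β is available). β defaults to 6, the conventional unsigned
  choice; `pick_power` implements the scale-free-topology criterion
  (smallest β whose log-log connectivity-frequency regression reaches
  R² ≥ 0.8, else the best-fitting candidate) for data-driven selection.
  Missing correlations contribute zero strength; the diagonal is zero so
  self-terms never enter connectivity.
* **Topological overlap**: TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)
  with l_ij the adjacency row dot product and k_i the row sum; TOM_ii := 1.
  Computed as a dense matrix product; validated to 1e-10 against a naive
  triple-loop transcription of the formula.
* **Clustering**: average-linkage hierarchical clustering of 1 − TOM
  (scipy). Module extraction is a branch-stability tree cut: every dendrogram
  subtree with ≥ `min_module_size` leaves is a candidate module, scored by
  its *stability* — the gap between the height at which the subtree forms
  and the height at which it merges into its parent. Long-stemmed branches
  are well-separated groups under average linkage. Candidates are accepted
  greedily in decreasing stability (ties: larger subtree, then smallest
  member id) if disjoint from accepted branches and with stability at least
  `min_gap` (default 0.01 dissimilarity units). Everything unaccepted is
  labeled background; the background is reported explicitly and never
  treated as a module. The cut adapts to branch shape rather than using one
  global height, is deterministic, and degrades sanely: uniform overlap
  yields no stable branch (all background), two perfect blocks yield exactly
  two modules. Module labels are Roman ordinals in decreasing size order.
  The default min_module_size is 30; validation on the compact 120-peptide
  benchmark uses 10 (a third of the planted module size) to match that
  network's scale.
* **Eigengenes**: first right singular vector of the module's z-scored
  member submatrix (complete rows only, constant rows dropped), unit norm,
  oriented so mean member correlation is ≥ 0. A spot check confirms it
  explains at least as much member variance as the second component.
* **Module–trait correlation**: Pearson r between eigengene and trait
  indicator; p from the t transform t = r·√(n−2)/√(1−r²), two-sided.
  Selection is signed — r > 0.55 and p < 0.1 — because negatively
  correlated modules are biologically distinct and reported separately;
  an absolute-value mode is available. Zero-variance traits are untestable.
* **Trimming**: module-induced graphs keep edges with TOM ≥ 0.1 (the rule
  removes strengths *below* the threshold, so equality survives); nodes
  isolated after trimming are dropped, with before/after counts reported.
* **Module hubs**: top-k (default 10) by degree and betweenness within the
  trimmed module network, plus the single greatest-connectivity hub.
* **MST**: Kruskal over the complete 1 − TOM module graph with edges sorted
  by (weight, node pair) so ties resolve deterministically.
* **Membership vs significance**: kME = corr(peptide, eigengene) against
  peptide significance = |corr(peptide, trait)|, with their cross-peptide
  correlation as a module-level trait-coherence summary.

## Ordination

PCA operates on samples as observations, peptides as variables,
mean-centered only — the data are already on a common log2-ratio scale — and
autoscaling is a flag, not the default. Decomposition is by SVD; component
signs are fixed by forcing the largest-magnitude loading positive.
Explained-variance fractions are eigenvalue shares. PLS-DA is a NIPALS
latent-variable extraction against a ±1 class indicator (two classes only,
coded +1 for the lexicographically first label), with X deflation between
components and weight-vector convergence at 1e-10 (500 iteration cap); when
X'y is numerically zero no component is extractable and the result is empty
rather than noise.

## Enrichment

The hypergeometric upper tail P(X ≥ m) is evaluated in log space with
lgamma-based binomial coefficients, so backgrounds in the hundreds do not
overflow; the valid support bounds (i ≥ max(m, n−(N−M))) are enforced
explicitly. Only annotated proteins enter the counts: query and background
are intersected with the namespace's annotated set before N and n are
formed, matching the definition of the test. Categories absent from the
background are skipped. No multiple-testing correction is applied by
default; Benjamini–Hochberg q-values are available behind a flag. Because
raw p-values are used, family size matters for calibration — see the
synthetic annotation design below.

## Synthetic data: what it emulates, and what it does not

The generator draws, on the log2-ratio scale:

* a design of 5 conditions (3 biofuel-class, 2 environmental) × 2 time
  points × 2 technical replicates = 20 samples, with binary traits (biofuel
  class plus per-condition indicators);
* per module, a latent profile = effect × standardized trait + √(1−effect²)
  × noise, built per biological sample and tiled over technical replicates.
  Noise components are drawn orthogonal to the whole trait span and, while
  sample-space dimensions last, to each other, so the *sample* correlation
  between a latent and its trait equals the requested effect exactly and two
  planted modules correlate only through their traits. Default effects
  follow the study layout: mostly positive biofuel-linked modules, one
  negative, plus environment-linked ones (pattern 0.8/0.7/−0.8/0.75/…);
* protein profiles = latent + N(0, 0.3²) per sample; peptide profiles =
  protein + N(0, 0.3²); background proteins are pure N(0, 1) noise. The
  implied within-module cross-protein correlation is
  1/(1 + σ_p² + σ_e²) ≈ 0.85 (`expected_module_signal`), and same-protein
  peptides correlate more strongly — the property that motivates
  peptide-level networks;
* independent per-cell missingness at rate 0.05, chosen so the
  complete-case fraction over 20 samples (~0.36) matches the core-set
  fraction typical of multi-condition iTRAQ studies;
* PPI edges Bernoulli at 0.3 within modules and 0.02 elsewhere;
* annotations in two namespaces: KEGG — four pathway categories, each
  concentrated in one module (membership 0.7 in-module, 0.01 elsewhere);
  COG — one uniform letter per protein. The KEGG family is deliberately
  small and sparse: with uncorrected p-values, min-p calibration over a
  family of K categories degrades roughly as K × the per-test level, so a
  compact family keeps null module-sized queries from producing spurious
  top hits (measured: ≥ 94% of 200 null draws have min p > 0.05).

Default scale is 8 modules × 12 proteins plus 100 background proteins with
1–10 peptides each (~1,100 peptides); the compact recovery benchmark is 4
modules × 10 proteins × 3 peptides, no background, seed 7. One RNG stream is
spawned per artifact (expression, missingness, PPI, annotation, peptide
ids), so changing, say, the PPI rates never perturbs expression values.

Not emulated: mass-spectrometer sampling, peptide detectability bias, iTRAQ
ratio compression, condition-dependent missingness, correlated (batchy)
noise, or annotation errors. Passing tests therefore demonstrate
correctness of the algorithms and calibration under the stated generative
model, not robustness to every artifact of real LC-MS/MS data.

## Validation design

Each non-trivial computation is checked against an independent oracle that
shares no code with the implementation: topological overlap against a naive
triple-loop evaluation (50 random matrices, n ≤ 40, 1e-10), betweenness
against explicit enumeration of all shortest paths (50 random graphs,
n ≤ 30, 1e-9), the hypergeometric tail against exact rational arithmetic
(every parameter combination with N ≤ 25, 1e-12, plus normalization of the
mass function), PCA against reconstruction and variance-sum identities,
the MST against Prim's algorithm, and module recovery against the planted
partition (adjusted Rand index ≥ 0.8 on the benchmark; in practice recovery
is exact). End-to-end determinism is asserted by running the full pipeline
twice and comparing manifest counts and module assignments.

Problem sizes in the validation scripts (50 oracle instances, N ≤ 25
enrichment sweep, ~1,100-peptide end-to-end runs) were chosen to exercise
the algorithms well beyond their closed-form cases while keeping the whole
suite runnable in well under a minute on one CPU.

## Known limitations

* The branch-stability tree cut is this package's own fully specified
  variant of dendrogram-shape-based module extraction; it does not reproduce
  the reference Dynamic Tree Cut implementation's hybrid refinements (PAM
  assignment of outlying leaves, deep-split levels). On data where modules
  overlap strongly it tends to fragment rather than merge.
* PLS-DA is two-class only, without cross-validated component selection;
  explained variance is reported on X, not Y.
* Enrichment assumes annotation categories are fixed sets; proteins with
  multiple categories count once per category.
* At 10 averaged samples the correlation estimates behind the full-scale
  network are noisy; study-scale module recovery is good but not exact
  (the compact benchmark, with less entangled structure, is recovered
  exactly).
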