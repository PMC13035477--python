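# Methods

This note documents the models, parameter choices and known limits of
`lymphochemnet`. It covers what each stage computes, what the synthetic
lymph-node generator does and does not emulate, and the numerical decisions
a maintainer would otherwise have to reverse-engineer.

## Attraction potentials

For each ordered pair of distinct cells (sender i, receiver j) within one
sample and each registry entry (ligand l, receptor r), the attraction
potential is `sqrt(x_i(l) * x_j(r))` on log-normalized expression
(`x = ln(1 + s·count/libsize)`, scale `s = 10,000`; the scale is a community
convention and configurable — nothing downstream depends on its exact value
because the geometric mean is positively homogeneous). Self-pairs are
excluded: a cell is either sender or receiver in a given pair. Pairs with
fewer than `min_lr_pairs = 4` strictly positive ligand–receptor entries are
dropped, samples are processed independently, and merging is pure row
concatenation with column alignment — cross-sample pairs can never arise.

The construction is quadratic in cells per sample. `downsample_per_type`
(default 100; desk-scale analyses in the tests and acceptance script use 60)
caps each cell type at a seeded random subset before pairing. Memory for the
score block is `n²·p` doubles (n cells after capping, p registry pairs).

The bundled registry holds 25 curated chemokine ligand→receptor pairs: the
four homeostatic ligands (CXCL13→CXCR5; CXCL12→CXCR4/ACKR3;
CCL19/CCL21→CCR7/ACKR4), the three IFN-inducible inflammatory ligands
(CXCL9/10/11→CXCR3, CXCL11→ACKR1) and common inflammatory/homing CC and CX3C
pairs classed "other". Registries are plain CSV (`ligand,receptor,class`)
and fully replaceable; one ligand may list several receptors.

## Pair space, clustering, diffuseness

The retained pair × ligand–receptor matrix is treated as a feature matrix:
PCA to `n_pcs = 20` components (centered, not variance-scaled; capped at the
number of feature columns), a cosine `knn = 30` nearest-neighbor graph on PC
coordinates, a UMAP layout computed from that same kNN graph (precomputed
neighbors are passed to UMAP), and Leiden community detection
(RBConfiguration) on the graph with cosine-similarity edge weights.

The default Leiden resolution is 0.1, deliberately coarse. Attraction
features are few and strongly structured: at resolution 1.0 the kNN graph
fragments each interaction program into sub-communities driven by which
ligand–receptor channels happen to be zero in a given pair (count-level
dropout), which is noise at the biological scale of interest — zone-level
interaction programs. At 0.02–0.1, planted follicular vs T-zone programs are
recovered with ARI ≥ 0.92 in 10/10 simulations. Resolution remains a
parameter. On a connected kNN graph, resolution → 0 collapses to a single
community; disconnected graph components always remain separate communities.

Cluster annotation is by the top-mean column: CXCL13–CXCR5 → follicle-like;
CCL19/CCL21–CCR7 → T-zone-like; CXCL9/10/11–any → inflammatory; an all-zero
cluster is unassigned; anything else is labeled `other:<pair>`. Ties break
lexicographically and are logged.

The **diffuseness score** of a patient is the exact mean Euclidean distance
between all unordered pairs of its cell-pair vectors in PC space, after
downsampling the patient's pairs to `fraction = 0.3` (seeded). Groups
reduced below 2 pairs are skipped with a warning. The mean distance is
computed blockwise (no approximation, no full distance matrix), so groups of
tens of thousands of pairs are fine. Diffuseness is computed on the merged
embedding's PC space and grouped per patient afterwards; it is
translation-invariant and scales linearly with the coordinates.

Entity contributions per cluster divide raw per-cluster entity counts by
each entity's total pair count before renormalizing, so unequal cohort sizes
do not dominate. The in-silico/spatial concordance scales both cell-type
frequency vectors to [0, 1] (min–max; z-scaling available) over shared cell
types before the Pearson correlation.

## Spatial neighborhoods

Composition vectors use the k = 20 Euclidean nearest neighbors (self
excluded; ties at the k-th neighbor resolve by table order). K-means with
k = 20 (`n_init = 10`, seeded) clusters the compositions; redundant clusters
are then binned by greedy agglomeration: repeatedly merge the pair of
clusters with the highest centroid Pearson correlation at or above the
threshold, recomputing centroids, until no pair qualifies.

The merge threshold default is **0.8**. With k = 20 neighbors a composition
fraction carries multinomial noise of sd ≈ sqrt(p(1−p)/20) ≈ 0.1, and
k-means sub-clusters of a single homogeneous zone have centroids separated
by about one sd of that noise, which puts same-zone centroid correlations at
roughly 0.78–0.89; a 0.9 threshold therefore fails to re-bin redundant
clusters, while 0.8 re-bins them and still never merges across zones (whose
centroid correlations stay ≤ ~0.6 apart from genuine boundary mixtures). On
synthetic zonated layouts the merged labels recover planted zones with
median ARI ≈ 0.8 over replicate layouts (follicle core and ring counted as
one follicle zone — k = 20 neighborhoods resolve zone-level, not
sub-follicle, structure); diffuse layouts collapse to 1–2 neighborhoods.

Enrichment per (neighborhood, cell type) uses the 2×2 membership × identity
table: odds ratio with Haldane–Anscombe 0.5 correction only when a table
cell is zero, reported as log₂; two-sided Fisher p-values,
Benjamini–Hochberg adjusted across the whole matrix.

Marker positivity is Otsu's threshold on a 256-bin histogram (positive ⇔
value > threshold). When the two intensity modes are separated by empty
bins, the between-class-variance maximum is attained on a plateau of
thresholds; any member classifies the data identically up to points in the
boundary bin.

The 20-μm ligand–receptor proximity score counts, for each cell c, neighbors
d within the radius with (c ligand⁺ ∧ d receptor⁺) ∨ (c receptor⁺ ∧ d
ligand⁺); a qualifying pair increments both cells once. Positivity defaults:
count ≥ 1 on raw transcript counts, value > 2 on normalized expression.

The KDE chemoattraction test uses a fixed-bandwidth isotropic 2-D Gaussian
KDE, `f(p) = (1/(n·2πh²)) Σ exp(−‖p−t‖²/2h²)`, written in-house because the
test needs an absolute bandwidth in μm and a closed form at a single point
(`1/(2πh²)`), neither of which scipy's factor-parameterized KDE provides.
Default bandwidth is Silverman's rule (mean per-dimension σ · n^(−1/6)),
overridable via `bandwidth_um`. Densities at ligand⁺ vs ligand⁻ sender
positions are compared with a two-sided Wilcoxon rank-sum test. Under a
uniform null the test holds its nominal size (≥ 90% of null simulations give
p > 0.05); planted attraction at n = 200 senders is detected at p < 0.01.

## Signatures and survival

Signature scores are per-column means of the signature genes present in the
matrix (missing genes dropped with a warning; bundled signatures:
homeostatic = CXCL12, CXCL13, CCL19, CCL21; inflammatory = CXCL9/10/11).
Clonotypes are expanded when observed in strictly more than 7 cells.
Regulon enrichment is a two-sided Fisher exact test of DEGs among regulon
targets within a gene universe, Bonferroni-adjusted across regulons in batch
mode.

The maximally selected rank statistic uses the log-rank-scores formulation:
per-subject scores `a_i = δ_i − Λ̂(t_i)` (Nelson–Aalen with ties), so the
standardized log-rank statistic of the split at cutpoint μ is a cumulative
sum of `a` in score order with hypergeometric (permutation) variance
`k(n−k)/(n(n−1))·Σ(a−ā)²`. Candidate cutpoints are distinct score values
whose low group holds between `min_group_fraction = 0.1` and 0.9 of subjects
(a common convention for the bound). The p-value for the maximal statistic
is a seeded permutation null (default 1,000 permutations; each permutation
is an O(n) cumulative sum), chosen over asymptotic approximations for
transparency and testability; the naive log-rank p of the selected split is
reported alongside, clearly labeled — the permutation p accounts for the
cutpoint scan, the naive p does not. The statistic is invariant under
monotone transformations of the score. Kaplan–Meier curves and the
two-group log-rank test come from lifelines; groups with zero events are
computed with a warning. Cox regression is out of scope; the stratified
table is exposed for external tools.

## Synthetic lymph-node generator

The generator defines the study conditions for all tests. It emulates:

* **Entity chemokine programs** — negative-binomial counts with
  (cell type, gene) means. rLN: homeostatic ligands confined to stroma
  (FDC: CXCL13 8, CXCL12 3; FRC: CCL19 7, CCL21 7, CXCL12 5; LEC/BEC low
  CCL21/CXCL12) and receptors on lymphocytes (B: CXCR5/CXCR4 6, ACKR3 3,
  CCR6 3; T: CCR7 6, CXCR4 5; T_FH: CXCR5 6). FL: homeostatic at 60% of rLN,
  a 2% rFRC population with inflammatory ligands at 40% of DLBCL. DLBCL:
  rFRC (8% of cells) with CXCL9/10/11 at 8/8/6, all homeostatic ligands at
  20% of rLN levels, CXCR3 6 on cytotoxic T cells, and ectopic CXCL13
  (mean 4) in a seeded 30% subset of T_tox. Sixty background genes
  (mean 0.5) provide library size.
* **Dispersion gradient** — NB dispersion θ = 4.0 (rLN), 2.0 (FL), 0.9
  (DLBCL). The gradient encodes the higher transcriptional heterogeneity of
  the malignant microenvironment and, together with the program structure,
  produces the diffuseness ordering DLBCL > FL > rLN (medians ≈ 11 / 10 /
  8.4 under the default desk-scale settings).
* **Spatial layouts** — homogeneous Poisson placement (default 0.005
  cells/μm² on a 1000×1000 μm field, ≈5,000 cells) with zone-conditional
  cell types: FDC-rich follicle cores ringed by B cells with T_FH admixture,
  an FRC/T-cell T zone, an optional LEC-rich sinus band; DLBCL mode is a
  single diffuse mixture. Marker intensities are two-component log-normals
  conditioned on cell type (negative log-mean 1.0, positive 2.5, sd 0.4).
  Transcript counts are Poisson with program means scaled by a log-normal
  per-cell quality factor (sd 0.4) plus 20 background genes (mean 3), so
  roughly a quarter of cells fall below the >50-transcript QC threshold and
  the filter is actually exercised.
* **Survival cohorts** — standard-normal signature scores; subjects below a
  planted cutpoint quantile have their exponential hazard multiplied by
  exp(effect) (baseline hazard 0.02/month → median ≈ 35 months); independent
  uniform censoring with the upper bound solved numerically so the expected
  censored fraction matches the request.

Not emulated: full transcriptomes, batch effects, doublets, segmentation
errors, cell-cycle or spatial expression gradients within a zone, and any
dependence between a cell's expression and its coordinates beyond cell type.
Passing tests therefore demonstrate that the algorithms recover structure of
the kind the generator plants at realistic noise levels — not performance on
real patient data, where registry coverage, ambient RNA and segmentation
quality add failure modes the generator does not model.

## Problem sizes and determinism

Desk-scale defaults used by the test suite and `scripts/acceptance.py`:
2,000 cells per synthetic sample with a 60-cells/type cap before pairing
(≈10⁵ directed pairs scored, ~10³–10⁴ retained per sample), 5,000-cell
spatial fields, survival cohorts of 150–600 subjects with 500–1,000
permutations, and 10 replicate seeds for ordering/recovery claims (medians
reported). Every source of randomness flows from one root seed (NumPy
`default_rng`); pipeline re-runs with identical config and seed are
byte-identical, including the UMAP layout (fixed `random_state`).

## Known limitations

* One ligand–one receptor registry entries only; multi-subunit receptors are
  out of scope.
* The diffuseness score depends on the PC space of the merged embedding;
  whether per-sample spaces would be preferable is a design choice — merged
  was chosen so distances are comparable across patients and entities.
* The ≥4-positive filter interacts with registry size: with small registries
  biologically real interactions supported by fewer channels are discarded.
* Greedy centroid merging is order-dependent in principle; the
  highest-correlation-first rule with centroid recomputation makes it
  deterministic, but pathological centroid configurations could merge
  differently under other linkage rules.
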