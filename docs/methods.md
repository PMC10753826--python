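# Methods

This note documents the models and procedures morelbiome implements, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter when reproducing
results.

## Amplicon preprocessing

The pipeline begins at a denoised ASV count table; read-level processing
(trimming, denoising, chimera removal) is upstream and out of scope. The
hygiene sequence is applied in a fixed order, with filtering before
normalisation so proportions are computed on the cleaned table:

1. **Control-based exclusion.** Any ASV with at least `min_count` reads
   (default 1) in any no-template control is removed, and the control
   samples are then dropped. This is deliberate presence-based exclusion,
   not abundance-ratio decontamination: a single contaminant read in a
   control disqualifies the ASV. The `min_count` override exists for
   datasets with known index bleed-through.
2. **Kingdom filter.** Only ASVs classified to Bacteria are retained;
   unclassified ASVs count as non-bacterial.
3. **Total-sum scaling.** Each sample's counts are divided by its library
   size. A zero-total sample is an error (it has no composition), reported
   by name.
4. **Genus agglomeration.** Proportions of ASVs sharing an assigned genus
   are summed; ASVs whose genus is missing or a placeholder token
   (`uncultured`, `metagenome`, `unidentified`, …; the list is
   configurable because such tokens vary by reference database) are pooled
   into one `unassigned` row. Per-sample sums are conserved exactly.

Both filters are idempotent, and TSS followed by agglomeration preserves
per-sample sums to 1 within 1e-9 (asserted by the `RelAbundanceTable`
container itself).

## Layered core community

Core membership at thresholds (p, d): a taxon is present in a sample when
its relative abundance strictly exceeds d (d is "the threshold above which
a taxon counts as present", so `>` rather than `>=`; both comparisons are
configurable since toolkits differ), and is a core member when the
fraction of samples where it is present — its occupancy — is at least p.
Thresholds are fractions internally; percent values convert at exactly
value/100.

The default grid is p ∈ {0.30, 0.35, …, 1.00} ×
d ∈ {0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50, 0.75, 1.00, 2.00, 5.00,
10.00}% (180 cells). Membership is monotone non-increasing in both
thresholds, which the test suite verifies against brute-force enumeration.

**Layer construction.** Collapsing a 2-D grid into nested layers is
genuinely under-determined, so two explicit modes are provided and the
chosen mode is recorded in the export:

* `diagonal` (default): walk from the strictest corner outward, pairing
  the k-th largest prevalence with the k-th largest detection value (the
  shorter grid index-mapped proportionally onto the longer). Monotonicity
  guarantees the resulting chain nests.
* `union-rank`: define a cell's strictness rank as the number of grid
  cells it dominates (both thresholds ≤ its own); layer k is the union of
  all cells with rank ≥ k. High rank = strict, so layers again nest by
  construction.

Consecutive identical member sets are collapsed in both modes.

**Innermost core.** The non-empty cell at the lexicographically highest
(p, d), prevalence leading — prevalence is treated as the primary
parameter — together with the maximum per-taxon occupancy among its
members. When computing cores on genus-agglomerated tables the pooled
`unassigned` row can be excluded from candidacy (the pipeline does so): it
is a bookkeeping aggregate of placeholder lineages, not a taxon, and
otherwise it would trivially occupy the innermost layer of every group.

Core computation defaults to the genus level (cores are reported as genus
names) with an ASV-level flag, since detection thresholds are interpretable
at either level.

## Bray–Curtis, NMDS, PERMANOVA

All three are implemented in the package rather than delegated, so their
exact conventions are pinned down; scipy's pairwise distances and
scikit-bio's PERMANOVA serve as independent cross-checks in the test suite.

* **Bray–Curtis** on TSS proportions: d(i,j) = 1 − Σ_f min(x_fi, x_fj),
  which equals the count formulation under TSS. Values lie in [0, 1].
* **NMDS** minimises Kruskal stress-1,
  √(Σ(d̂_ij − δ_ij)² / Σ δ_ij²), where δ are configuration distances and
  d̂ the disparities from pool-adjacent-violators isotonic regression of δ
  on the rank order of the observed dissimilarities. Optimisation is the
  Guttman transform; the first start is classical metric scaling, the rest
  random Gaussian configurations (defaults: k = 2, 20 restarts, tol 1e-7
  on stress change, 300 iterations). An iteration is accepted only if
  stress decreases, so the stress trajectory is non-increasing by
  construction; an uphill step terminates the run at the previous
  configuration. The returned configuration is centred and scaled to unit
  RMS radius; stress is invariant to that scaling only through the
  disparities, so reported stress is always recomputable from the returned
  coordinates (tested to 1e-8).
* **PERMANOVA** uses Anderson's decomposition:
  SS_total = (1/N) Σ_{i<j} d²_ij, SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,
  pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a)). The p-value is
  (1 + #{F* ≥ F}) / (1 + B) over B uniformly random unrestricted label
  permutations (default B = 999, the conventional choice). Permutations
  are evaluated vectorised via one-hot group indicators, so the 500-
  replicate calibration check runs in seconds. Degenerate geometry behaves
  as the algebra dictates: with all pairwise distances equal the pseudo-F
  is exactly 1 and p = 1; with zero within-group distances F is infinite
  and only block-preserving permutations tie it.

The distance metric and taxonomic level are recorded in the ordination
output; the PERMANOVA factor defaults to sample type but any metadata
column can be tested.

## Pangenome stage

Bitscores are consumed, not computed — alignment is a solved upstream
problem. The stage is:

1. **minbit**: score(a,b) / min(self(a), self(b)); symmetric whenever the
   raw score is, equal to 1 for self-comparison. Edges with minbit below
   the threshold (default 0.5) are dropped; when both orientations of a
   pair are scored the larger bitscore is used.
2. **MCL** on the surviving weighted graph: the walk matrix is
   column-stochastic with self-loops at each node's maximum incident edge
   weight (1 for isolated nodes); iterate expansion (power 2) then
   inflation (entrywise power 2.0, renormalise), pruning entries < 1e-8,
   until the largest entry change < 1e-6 or 100 iterations (the result
   then carries `converged=False` rather than failing). Clusters are the
   connected components of the limit matrix's non-zero support; singletons
   are legitimate clusters. Inflation 2.0 and expansion 2 are the
   classical MCL defaults; all knobs are exposed. Higher inflation yields
   finer partitions (tested as non-coarsening on bridged-clique fixtures).
3. **Binning** by genome occupancy (presence = ≥ 1 member gene): core
   (all genomes), per-genome unique (exactly one), optional group-core
   (all of a given genome subset and no others), accessory (the rest).
   Bins partition the cluster set.
4. **KEGG-module completeness**: a module is an ordered list of steps,
   each a set of alternative KOs; a step is satisfied when any alternative
   is annotated in the genome; completeness = satisfied/total, complete at
   ≥ 0.75. The full KEGG boolean grammar (nested AND/OR, optional steps)
   is deliberately not implemented — the simplified stepwise form is what
   threshold-based completeness needs. Completeness is monotone in the KO
   set.
5. **Category tallies**: per-genome hit counts for arbitrary annotation
   category labels (CAZy-family style), with per-genome totals.

## Synthetic-data generators

**Community generator.** Emulates a fungal-structure bacteriome survey.
Defaults are the study conditions: 26 mycelium, 10 fruiting-body and
8 sclerotia samples plus 2 no-template controls; a Pseudomonas-like
dominant planted in mycelium (occupancy π = 0.95) and sclerotia (π = 1.0)
at mean relative abundance μ = 0.2 with a Ralstonia-like secondary core
(π = 0.7, μ = 0.05); a diffuse two-genus fruiting-body core (π = 0.55,
μ = 0.02 each). Per sample: each planted taxon of that type is present
with independent probability π and claims μ of the target composition;
contaminant taxa appear at low abundance (0.002, occupancy 0.5); the
remaining mass goes to 40 background genera with log-normal(0, 1.5)
weights, each genus present in a Bernoulli(0.3) subset of samples. The
realised composition is Dirichlet(200 × target) and counts are multinomial
at a uniform depth in [2000, 20000]. Controls contain only the contaminant
taxa (guaranteed ≥ 1 read each). A few Eukaryota ASVs and placeholder-genus
("uncultured") ASVs exercise the kingdom filter and the agglomeration
pooling.

Rationale for the free values: 40 genera with log-normal sd 1.5 gives the
steep rank-abundance curve typical of 16S surveys at genus level;
concentration 200 yields mild compositional overdispersion; depths span
typical MiSeq per-sample yields. Background occupancy 0.3 encodes the high
between-sample turnover reported for fruiting-body communities — the
innermost fruiting-body core is then governed by the planted diffuse core
rather than by shared background, which is the regime the method is meant
to resolve.

What the generator does **not** emulate: read-level error, chimeras,
phylogenetically correlated abundances, abundance-correlated occupancy,
cross-talk of real samples into controls, or multiple ASVs per genus with
distinct dynamics. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure under
Dirichlet-multinomial noise — not robustness to denoising artefacts or
taxonomic misassignment in real surveys.

**Pangenome generator.** Defaults emulate a six-genome panel at desk
scale: 40 single-copy core clusters, 8 unique clusters per genome, and a
12-cluster block specific to genomes G1–G3 (mirroring a closely related
subgroup). Within-cluster bitscores are N(300, 15), cross-cluster pairs
N(30, 10) (floored at 1), and every self-score is 1.1 × the largest score
involving that gene, so self-scores dominate pairwise scores by
construction and within/between minbit distributions are well separated at
the 0.5 threshold. Configurations where the within mean does not exceed
the between mean, or with self-score scale < 1, are rejected. KO
annotations ride on clusters (one KO per cluster), and generated modules
alternate between all-core steps (complete in every genome) and modules
with two group-specific steps (complete only inside the group, 2-of-4
= 0.5 outside). Gene ids encode their planted cluster, so ground truth is
recoverable without side channels.

Not emulated: paralogy (multi-copy clusters), domain-level chimeras,
homology detection noise structured by sequence length, annotation
transfer errors.

## Pipeline and reproducibility

`run_pipeline` executes generate → preprocess → core (per structure type)
→ ordination/PERMANOVA → pangenome, writing per-stage artifacts and a
manifest with the effective configuration, seeds, package version and a
SHA-256 checksum per artifact; identical configuration and seed reproduce
identical checksums (timestamps excluded). A failing stage aborts with the
stage named; earlier artifacts are preserved. One integer seed drives all
randomness; stage seeds are small fixed offsets of it.

Problem sizes used in the validation suite — surveys of 44 samples ×
~50 taxa, 100-replicate contrast checks, a 500-replicate PERMANOVA null
calibration at 999 permutations, pangenomes of ~320 genes — were chosen so
the planted effects are comfortably resolvable at desk scale while the
whole suite runs in well under a minute per check.

## Known limitations

* Core layers summarise a 2-D threshold grid as one chain; taxa whose
  occupancy/abundance trade-off is non-monotone along the chosen diagonal
  can appear in a cell of the grid yet in no layer boundary. The full grid
  export exists for exactly that reason.
* NMDS is a local optimiser; restarts mitigate but do not eliminate local
  minima. Stress, seed and restart count are always reported.
* PERMANOVA assumes exchangeability under the null; with strongly unequal
  group dispersions the pseudo-F conflates location and dispersion (no
  PERMDISP companion test is provided).
* Dense MCL is quadratic in gene count; it is intended for panels of a
  handful of genomes (thousands of genes), not whole-clade pangenomes.
* The module grammar ignores KEGG's optional and nested-boolean steps;
  completeness values for modules relying on those constructs would differ
  from KEGG-native estimators.
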