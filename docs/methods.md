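# Methods

## Pipeline and model

Given two studies' expression matrices (genes × samples, same platform /
gene universe) and their DEG lists, the pipeline is

    pool = union of DEG lists ∩ genes measured in both studies
    network(r) = graph on pool, edge iff |Pearson corr| ≥ r
    R = PageRank(network, d = 0.85)
    RSOG = Σ ranks of the overlapping genes
    PRSOG = upper-tail p-value of RSOG under random k-gene draws from the pool

The quantity metric POG₁₂ = k/l₁, POG₂₁ = k/l₂ is reported alongside
(displayed rounded to two decimals; stored unrounded; the reported
"mean POG" is the arithmetic mean of the two directions).

### Correlation network

* **Sample source.** Which samples feed the pairwise correlations is a free
  choice; the default `pooled` concatenates both cohorts' samples, which is
  symmetric in the two studies and uses all the information. `study1` /
  `study2` restrict to one cohort. The choice is logged.
* **Sign handling.** Default is absolute thresholding, |ρ| ≥ r, the usual
  co-expression convention (anti-correlated regulators stay connected);
  signed thresholding is available. The bound is closed (with a 1e−12
  floating-point guard so r = 1 admits numerically perfect correlation).
* **Degenerate genes.** A zero-variance gene has undefined correlations: it
  keeps its node but gets no edges, with a warning naming it.
* Pearson is the default statistic; Spearman is available.

### PageRank

Power iteration from the uniform vector 1/N on the column-stochastic
transition matrix (each undirected edge is two directed links of weight
1/degree), with teleportation (1 − d)/N, d = 0.85. Convergence is declared
when the L1 change between successive iterates falls below `tol` (default
1e−10, max 1000 iterations; non-convergence returns the last iterate with
`converged=False` and a warning, never silently). The final vector is
renormalized to sum exactly 1.

Isolated genes (degree 0) have no outgoing links; two treatments are
exposed:

* `teleport_redistribute` (default, the standard convention): dangling mass
  is spread uniformly; every gene keeps the floor (1 − d)/N.
* `self_absorb`: dangling mass stays on the gene itself, pinning isolated
  genes at the uniform share 1/N before renormalization while connected hubs
  grow past it.

The two modes agree on connected networks. On sparse, high-threshold
networks they differ for isolated genes; which a given published analysis
used is generally not recoverable from reported near-zero isolated-gene
ranks, so neither mode claims to reproduce any particular external number.

Correctness is checked two independent ways: a dense linear solve of
(I − dT)x = (1 − d)/N·1 (max-norm ≤ 1e−8 on random graphs up to N = 50),
and networkx's PageRank on dangling-free graphs.

### The resampling null and PRSOG

Each null draw picks k distinct genes uniformly from the pool (without
replacement within a draw; with-replacement is available but off by
default) and records the rank sum. Default 10,000 draws; μ and σ are the
sample mean and SD. PRSOG is the upper-tail probability:

* `normal_tail` (default): P(X ≥ RSOG) for X ~ N(μ, σ), computed through
  scipy's survival function (complementary-error-function route). This is
  deliberate: a naive `1 − CDF` subtraction underflows to 0 or machine
  epsilon for strong signals, producing meaningless reported values like
  1.1e−16. σ = 0 (empty or uniform networks) is handled by sign comparison
  with a degeneracy warning.
* `empirical`: (#draws ≥ RSOG + 1)/(draws + 1), the add-one correction, so
  the p-value is never exactly 0 and is exactly uniform on its support when
  the observed overlap is itself a uniform draw.

An empty overlap yields RSOG = 0 and PRSOG = 1 without resampling.

### Gene classification

For gene i the importance p-value is the probability that a random pool
gene outranks it. Each bootstrap replicate resamples N ranks with
replacement and computes the strict-exceedance fraction; the reported
p-value is the mean over replicates (default 10,000) with its SD. The mean
converges to the plug-in fraction #(rank > rankᵢ)/N; the replicate noise is
what the SD column quantifies. Ties share the exceedance count, so equally
ranked genes get equal p-values. Classes: significant p ≤ 0.1, wrong
p ≥ 0.9, common otherwise (thresholds configurable). With tie-free ranks
the pool splits ≈ 10% / 80% / 10% by construction; the informative quantity
is the class composition of the *overlap* relative to the pool.

### Heavy-tail fits

Power-law (C x^−α), exponential (λe^−λ(x−x_min)), and log-normal truncated
to [x_min, ∞) are fitted to the rank tail. x_min is chosen by minimizing
the K-S distance between the empirical tail and the family's ML fit over
candidate cutoffs (the Clauset–Shalizi–Newman recipe; candidates are the
unique rank values, thinned to ≤ 100, always leaving ≥ 10 tail points).
ML estimators: α = 1 + n/Σln(x/x_min); λ = 1/mean(x − x_min); truncated
log-normal by Nelder–Mead on the exact truncated likelihood, evaluated
through log-survival functions to avoid underflow. The K-S p-value is a
parametric bootstrap (default 100 resamples) that refits the parameters
per resample with x_min held fixed — re-selecting x_min per resample
(the full Clauset procedure) costs ~100× more for little change at these
tail sizes. Fitting refuses non-positive ranks (isolated genes under
near-zero handling) and tails below 10 points.

**Limitation:** with a free x_min, the truncated log-normal can mimic a
power-law tail (and vice versa) to within K-S distances smaller than
sampling noise; K-S-based selection between those two families is not
reliable and the package does not claim it is. Discrimination against a
clearly mis-specified family (power-law vs exponential) is reliable and is
what the test suite asserts.

## Synthetic data generator

`datagen` emulates the two-cohort design the method targets: a shared gene
universe, block-correlated modules, planted DEG lists with an exact overlap
count, and MCAR missing values.

* **Expression model.** Genes are unit-variance Gaussian with a
  single-factor block structure: within a module, pairwise correlation is
  exactly `within_module_corr`; across modules ≈ 0; singleton genes are
  independent. The method consumes only pairwise correlations, so Gaussian
  blocks are the minimal faithful generative model.
* **Modules.** `module_gene_frac` (default 0.6) of genes are assigned to
  `n_modules` blocks, the first block holding a double share so a unique
  largest module always exists; the rest are singletons.
* **DE planting.** Each study's DEG genes get a mean shift of `effect_size`
  (default 2) SD in that study's case samples (half of each cohort). The
  convenience selector recovers them, enabling end-to-end tests.
* **Overlap placement.** `high_rank` fills the overlap from the largest
  modules (post-threshold hubs, hence top PageRank); `low_rank` from
  singletons (isolated nodes); `random` uniformly. Extras are drawn
  uniformly from the remaining genes, disjoint between the lists, so
  |degs₁ ∩ degs₂| = k exactly.
* **Defaults** mirror a two-cohort breast-cancer comparison: 2000 genes,
  cohorts of 53 and 180 samples, DEG lengths 963/856 with overlap 308
  (POG pair 0.32/0.36), 10 modules at ρ = 0.7, 1% missing values.
* Reproducibility: one integer seed, split into per-stage substreams; same
  seed ⇒ bit-identical output.

**What the generator does not model:** probe-level noise, batch effects,
platform normalization, non-Gaussian marginals, or realistic hub-degree
distributions beyond what block structure induces. Passing tests show the
statistics behave as designed under exchangeable Gaussian blocks — not that
any particular real pair of studies is reproducible.

**A real confounder, reproduced faithfully.** Genes planted as DE in *both*
studies share a case/control mean-shift pattern, which by itself induces
mutual correlation (≈ ρ·shift²/(shift² + var) pooled) — so a "randomly
placed" overlap with a strong planted effect is *genuinely* more connected
and more important than the pool average, and PRSOG correctly flags it.
Co-expression networks built on mixed case/control samples always conflate
differential expression with co-regulation. Consequently the calibration
and placement-contrast tests disable the mean shift (`effect_size=0`), the
condition under which random placement actually makes overlap genes
exchangeable with the pool; the rank-conditional calibration test draws
overlap sets uniformly from a fixed pipeline-built rank vector, where
exchangeability holds by construction.

## Numerical and design choices

* kNN imputation (default k = 15) is gene-wise: a missing cell (g, s) is
  the unweighted mean over the k genes nearest to g — Euclidean distance
  over mutually observed samples, ties broken by gene-identifier order,
  donors restricted to genes observed at s. A gene with no observed values
  is an error; k beyond the available genes falls back to all of them with
  a warning. Checked cell-for-cell against a brute-force oracle.
* The DEG selector ranks genes by |mean difference| / (stabilized SD), with
  the stabilizer s₀ set to the median per-gene SD (SAM-flavoured
  variance moderation); paired design uses the paired differences. It
  returns strictly fewer than `max_genes` genes (top `max_genes − 1`).
  It is plumbing for synthetic experiments, not a reimplementation of SAM.
* The end-to-end threshold-sweep test sets the generator's module
  correlation to 0.95: the sweep is only informative if the module
  structure survives the highest threshold (at ρ = 0.7 the network is
  empty at r = 0.9 and the statistic degenerates, which a separate test
  covers).
* Problem sizes in tests and the acceptance script (300–500-gene universes,
  40-sample cohorts, 2000-replicate calibrations, 10,000-draw nulls) are
  chosen so every statistical property is measured at comfortable Monte
  Carlo precision on a laptop-scale run; the statistics themselves are
  size-free.

## Known limitations

* PRSOG conditions on the network; uncertainty in the network itself
  (finite-sample correlation noise) is not propagated.
* The normal-tail mode extrapolates far beyond the resampled support; the
  empirical mode is bounded below by 1/(draws + 1). Both are reported
  honestly rather than clipped.
* Which samples should feed the correlations, and signed vs absolute
  thresholding, are genuinely open modelling choices; defaults are
  documented above and logged at run time.
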