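# Methods

`gutnet` analyses a samples x bacterial-genera read-count table — here the
gut microbiota of eight sympatric tephritid fruit-fly species from Reunion
Island, each sampled in the laboratory and in the field — and asks how much
of the community structure is explained by host phylogeny, host
specialization (host-plant range) and sampling environment.  This note
records the models, the parameter choices that matter, and the design
decisions taken where the methodology was genuinely open.

## Data model and filtering

The central object is a samples-in-rows table of non-negative integer read
counts (`ReadCountTable`); row sums are per-sample sequencing depths.
Genus-level counts can be rolled up to family/order/class/phylum through a
`TaxonomyTable`, conserving total reads.

Low-abundance filtering removes genera that never reach a relative-abundance
threshold.  The threshold is motivated by mock communities: the largest
relative abundance a false-positive (misassigned or contaminant) taxon
attains in mocks (0.001 by default) bounds what can be trusted.  Because
that rationale is per-sample, the default rule retains a genus iff its
within-sample relative abundance reaches the threshold in at least one
sample; a `mode="global"` flag applies the threshold to the pooled fraction
instead.  Which of the two the original genus filter used is not documented;
both are available and per-sample is the default.

## Presence-absence ensembles

Read counts are noisy proxies of abundance, so community analyses also run
on presence-absence matrices.  Binarization happens after rarefaction to a
common depth (default 3000 reads), by true without-replacement subsampling
(multivariate hypergeometric) — a sample at exactly the target depth is
returned unchanged.  A genus is called present iff its rarefied count is
*strictly greater* than the threshold (default 3): the calibration logic is
"false positives never exceeded three reads", so counts of at most 3 are
noise.  An `inclusive=True` flag gives the >= reading.

The presence threshold can be recalibrated from mock runs: the threshold is
the maximum count any known false-positive taxon attains across (default
100) rarefactions of every mock table.  The number of rarefaction replicates
used in the original calibration is undocumented; 100 is the default here.

Since rarefaction is random, all presence-absence analyses run on an
ensemble (default 1000 matrices).  Matrix *i* is rarefied with seed
`master_seed + i`, recorded in its provenance, so ensembles are reproducible
and extendable.

## Diversity

Diversity is reported as order-1 Hill numbers, exp(Shannon entropy) with
natural logs ("genus equivalents"; the log base cancels in exp-units).
Gamma is partitioned multiplicatively: with equal unit weights,
alpha = exp(mean within-unit entropy), gamma = exp(entropy of the mean
profile) and beta = gamma/alpha, the effective number of completely distinct
communities (1 <= beta <= number of units).  Equal weights are the
convention under which gamma = alpha x beta holds exactly at q = 1;
group profiles are equal-weight means of member samples' relative-abundance
vectors.  Confidence intervals use a hierarchical bootstrap: samples are
resampled within units with replacement, then each chosen sample's reads
are resampled multinomially at its observed depth; 2.5/97.5 percentiles over
(default 1000) replicates.  A flag restricts resampling to the read level.

Ordination: Bray-Curtis dissimilarity on relative abundances, embedded by
non-metric multidimensional scaling (SMACOF majorization with isotonic
regression on dissimilarity ranks; one classical-scaling start plus random
starts, best of 20 by default).  The reported stress is Kruskal stress-1 in
[0, 1], recomputed in-package from the final configuration.

## Community detection

Presence-absence matrices are bipartite sample-genus networks.  Communities
are found by Newman's leading-eigenvector method: recursive bisection by the
sign pattern of the dominant eigenvector of the generalized modularity
matrix, accepting a split only when the dominant eigenvalue is positive and
modularity Q increases.  The modularity null is the standard unipartite
degree model k_i k_j / 2m applied to the bipartite adjacency (matching
common igraph usage on incidence graphs) rather than a bipartite-specific
null.  By default no fine-tuning follows the spectral splits, mirroring the
plain method; `fine_tune=True` adds Kernighan-Lin sweeps per bisection and
a final greedy node-moving pass.  Recursive bisection is a heuristic: on
small random graphs its Q typically lands within ~0.002 of the exhaustive
optimum on average, but isolated instances need a 3-way split no sequence
of improving bisections reaches (a limitation shared by other
implementations of the algorithm).

Ensemble results are aggregated into a consensus matrix: the fraction of
matrices in which each sample pair co-clusters.  The consensus partition
cuts an average-linkage dendrogram of (1 - co-clustering probability) at
0.5 by default; the modal (most frequent exact) partition is also
available.  Group counts per ensemble member count sample-node groups only,
ignoring genus-only groups.

## Null models

Binary matrices are randomized by the curveball algorithm: each trade picks
two rows, pools the columns exclusive to each, and redeals a random subset
of the original sizes, preserving both margins exactly.  Default trades per
chain: 5 x number of rows (a standard mixing heuristic; the original count
is undocumented).  Log-count matrices are randomized by Gaussian sampling
around the margin product m_ij = rowmean_i x colmean_j / grandmean with the
pooled residual standard deviation (a cell-free constant is available),
truncated at zero; the exact construction is undocumented in the source
methodology, and these choices are this package's documented stand-ins.
Empirical p-values use the add-one form (1 + #extreme)/(1 + N), which never
returns 0.

## Congruence and ordination tests

Partition congruence uses NMI with the 2I/(H1+H2) (arithmetic-mean, Danon)
normalization; two trivial partitions give 1, exactly one trivial gives 0.
Per ensemble matrix, communities are detected and compared to an external
classification; the mean NMI is taken over the whole ensemble, while mean
p-values compare (default) 100 observed matrices against 1000 curveball
randomizations each.

Canonical correspondence analysis treats the sample-by-group indicator as
the response: correspondence-standardized, optionally residualized on
conditioning factors (partial CCA), then projected on the row-mass-weighted
design.  For a single unconditioned categorical factor the constrained
chi-square equals the Pearson chi-square of the factor x group contingency
table divided by n — used as an exact oracle in the tests.  Printed F
statistics from the original decomposition are not reproducible under any
single df convention (the chi-squares are); two conventions are provided
("dummy": df1 = design dfs, df2 = n - 1 - df1 - df_cond; "rank": df1 = rank
of the constrained solution) and chi-square is the validated surface.
Row-permutation p-values follow the reduced-model scheme (residualize on
the conditioning factors, permute response rows).  Edge-permutation
p-values re-detect communities on degree-preserving null matrices and are
only computed for row-significant effects: they separate "richness" effects
(explained by node degrees alone) from "affinity" effects (surviving
degree-preserving randomization).

SVD reduction factorizes the incidence matrix as L R^T with
L = U_k S_k^1/2, R = V_k S_k^1/2.  Reconstructed networks keep the observed
edge count (the largest entries of L R^T; no published threshold exists).
The rank is chosen as the first local maximum of the mean NMI between
communities of reconstructed and original matrices over a small rarefied
ensemble.  Redundancy analysis of L on the host factors uses column-centered
least squares; explained variance is Ezekiel-adjusted with m set to the
*rank* of the centered dummy design rather than the raw dummy count — in
this study design specialization and phylogeny are partially collinear (the
Solanaceae specialist is exactly the *Neoceratitis* group), and using raw
dummy counts would bias adjusted R² visibly negative for random data (the
unbiasedness test in the suite verifies mean adjusted R² ~ 0).  Venn
fractions solve the inclusion-exclusion system on adjusted R²; individual
fractions may be negative and are reported as-is.

## Gaussian latent block model

The weighted analysis biclusters log10(reads + 1) with a Gaussian latent
block model: rows and columns carry latent groups, each (row-group,
column-group) block has its own mean and variance (floor 1e-6).  Fitting is
mean-field variational EM; the variational bound is checked to be
non-decreasing at every iteration (the check is suspended on iterations
where the variance floor binds, which can formally break monotonicity).
The best of (default 25) restarts by the bound is kept: restart 0 is seeded
by k-means on rows and columns, the rest are random hard assignments.
Model choice maximizes ICL = completed log-likelihood
- (K-1)/2 ln n - (L-1)/2 ln p - KL ln(np), with ties broken toward smaller
K + L.

## Synthetic data

The generator mirrors the study design: 16 samples = 8 species x
{laboratory, field}, with the species-to-phylogeny-group mapping of the
real system; ~46 genera in 3 phyla.  Composition has three layers:

- a core block (~20% of genera, one dominant Enterobacteriaceae-like
  family) carrying `core_fraction` (default 0.69) of expected reads in
  every sample; the non-core baseline is analytically deflated by the
  expected block-enrichment factor so the core share is invariant to
  `block_effect`;
- four group-specific genus blocks enriched by `block_effect` (natural-log
  scale, default 2.5) in samples of the matching phylogeny group;
- a random quarter of non-core genera linked to environment, shifted by
  +/- `env_effect`/2 (default 1.0) between field and laboratory.

Per-sample compositions are Dirichlet-multinomial (concentration
`dispersion`, default 50 — substantial overdispersion, as in real
metabarcoding data) at log-uniform depths in 3250-36902 reads.  Core genera
are guaranteed present in every sample.  The planted sample partition,
genus blocks and environment-linked genera are returned as ground truth.

`SyntheticConfig.planted_recovery` fixes the conditions for recovery
experiments: no environment effect, dispersion 300, fixed depth 10000 and
baseline spread 0.1, so the planted blocks are genuinely homogeneous — what
a parameter-recovery experiment should isolate.  The two clustering routes
see the enrichment differently.  The presence-absence/modularity route
needs the enrichment to separate *at the presence threshold*: with
enrichment 3 a cross-block genus still has expected rarefied count
3000 x 0.31/209 ~ 4.4 > 3, so binary recovery only becomes reliable at
enrichment ~4.5 (cross-block expectation ~1.1).  The weighted/LBM route is
sharpest at moderate enrichment (3), where cross-block cells retain
Gaussian-like variation; at stronger enrichment they collapse onto exact
zeros at the variance floor and ICL over-splits columns.  At these
respective settings consensus clustering recovers the planted 4 groups
(NMI >= 0.9) and ICL selects the planted (K, L) = (4, 5), each in >= 90% of
seeds.  What passing these tests does *not* show: recovery under real-data
features the generator omits — taxonomic misassignment, chimeras, batch
effects between runs, depth-driven heteroscedasticity of log counts (which
demonstrably blurs LBM column groups at default settings), and phylogenetic
correlation among genera.

Mock runs draw one multinomial sample over the expected taxa plus a small
false-positive pool.  The default pool holds six taxa at 6.5e-5 expected
relative abundance — far below the 0.001 ceiling — so each has mean
rarefied count ~0.2 at depth 3000 and the calibrated presence threshold is
3 for most seeds (Poisson tail: P(X >= 4) ~ 5e-5 per draw).

## Numerical choices and scales

- All randomness flows from explicit seeds; derived seeds are
  `master + index` and are recorded in provenance.
- Spectral splits stop at eigenvalue <= 1e-10 or Q gain <= 1e-12; group
  relabeling is canonical (size, then smallest member).
- The test suite and the acceptance script run scaled-down replicate counts
  (e.g. 25-50 recovery seeds, 200-500 calibration replicates with 100-200
  nulls, 100-500-matrix ensembles), sizes chosen so the full statistical
  checks complete in minutes while keeping Monte-Carlo error well inside
  the asserted tolerances.

## Known limitations

- Degenerate LBM blocks (constant cells) sit at the variance floor; their
  likelihood contribution is then floor-dependent.
- The consensus dendrogram cut at 0.5 can merge groups whose co-clustering
  probability straddles the cut; the modal partition is the robust
  alternative for strongly multimodal ensembles.
- Edge-permutation tests inherit the cost of re-detecting communities per
  null matrix; at full published scale (100 x 1000) they are an
  overnight-class computation and are run scaled down here.
- The F-statistic df convention is not settled (see above); comparisons
  across software should use the constrained chi-square.
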