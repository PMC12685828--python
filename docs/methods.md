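# Methods

This note documents the statistical procedures, the synthetic-data
generator, the numerical choices, and the places where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design assumed throughout

Samples come from a balanced factorial: three cropping systems
(W = wheat monoculture, S = soybean monoculture, SW = 6:2
wheat–soybean intercropping) × two sampling locations (bulk,
rhizosphere) × b blocks, one sample per cell.  The six
treatment-by-location groups are labelled W, SW, S, RW, RSW, RS in a
fixed order so letter displays and reports are comparable across
tables.  Two amplicon domains are carried in parallel (bacterial 16S,
eukaryotic 18S); all analyses treat them independently.

## Soil-property statistics

`two_factor_block_anova` fits the fixed-effects model
y ~ block + location × system.  Blocks are fixed, not random: with
three blocks a variance component is essentially unestimable, and the
additive fixed term removes the block means exactly as a randomized
complete block analysis should.  Balance makes the factor sums of
squares orthogonal, so they are computed directly from cell means and
the decomposition into block + L + T + L×T + residual is exact (tested
to 1e-8 relative).  If the residual mean square is exactly zero the
table is flagged `degenerate` and each term's F is reported as 0 (term
absent) or ∞ with p = 0 (term present) rather than NaN from 0/0.

The post-hoc is *unprotected* Fisher's LSD: pairwise t statistics with
the pooled residual mean square and its degrees of freedom, no
multiplicity correction within a column.  That convention matches the
letter displays agronomy tables typically print; it is anticonservative
across 15 pairwise tests and should be read as a display convention,
not a family-wise error guarantee.  Compact letters are assigned by the
insert-and-absorb algorithm, which guarantees the defining property —
two groups share a letter **iff** their pairwise test is
non-significant at α = 0.05 — verified exhaustively on random fixtures
in the tests.

Marginal means are unweighted means of the location × system cell
means; under balance these equal the raw level means, and they
reproduce the published enzyme marginals (urease rhizosphere 80.7,
sucrase rhizosphere 1.71, microbial P bulk 8.54) from the printed
cells.  Percent differences are 100·(a−b)/b reported at one decimal;
computed from the published TP means (1.58 vs 1.31) this gives 20.6%,
which is the value this package reports.  (The source trial's own text
gives 20.6% in the results and 19.8% in the conclusion; the
discrepancy is in the source, and we do not silently match either —
the computed value stands.)

## Diversity

Shannon entropy uses natural log by default; a `base` option exists
because different toolchains print bits or nats and the choice is often
undocumented.  Simpson is the Gini–Simpson form 1 − Σp².  Chao1 uses
the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) and therefore needs
raw counts; it is meaningless after relative-abundance transformation.
No rarefaction is applied by default — the upstream pipelines this
mirrors are silent on the point — but seeded rarefaction
(multivariate hypergeometric, i.e. subsampling without replacement) is
available and recorded.

PCoA applies Gower double-centering to −d²/2 and an
eigendecomposition; coordinates are eigenvectors scaled by √λ over the
positive eigenvalues only.  Negative eigenvalues (Bray–Curtis is
non-Euclidean) are reported but excluded from coordinates, with no
Lingoes/Cailliez correction — the simplest defensible default, and the
discarded magnitude is visible to the caller.  Eigenvalues below
1e-10·max|λ| are treated as zero.

PERMANOVA is the one-way distance-based partition:
SS_total = Σ_{i<j} d²_ij / n, SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g,
pseudo-F = (SS_b/(k−1))/(SS_w/(n−k)).  The p-value uses the
add-one estimator (1 + #{F* ≥ F})/(1 + N), so p > 0 always and its
resolution is 1/(N+1).  Permutations are unrestricted (no block
strata), matching the default of the standard distance-based MANOVA
implementations; samples are processed in sorted-sample-id order so the
result is invariant to input ordering and group renaming under a fixed
seed.  Type-I error is verified to sit inside the 95% binomial CI of
0.05 over 500 simulated nulls.

## LEfSe-style biomarker discovery

Stage 1 is a per-feature Kruskal–Wallis H test (tie-corrected,
chi-square reference) on relative abundances across classes; a feature
constant across samples is defined to have p = 1.  Stage 2 computes a
bootstrap LDA effect size on features passing p < α: per bootstrap
(2/3 of each class, ≥ 2 per class, 10 redraw attempts), a one-axis
linear discriminant is fitted (tiny jitter breaks collinearity, as the
reference tool does); the per-feature score is
½(|w_f·Δ_f| + |Δ_f|) with w the unit-norm discriminant direction and
Δ_f the class-mean difference of the feature in ppm (relative
abundance × 10⁶), maximized over class pairs for ≥ 3 classes; the
effect is log₁₀(1 + mean score), thresholded at 2.0 (inclusive).
The enriched class is the class with the highest overall mean
(one-vs-rest semantics).  The original tool's within-class subclass
(Wilcoxon) stage is omitted: this design has no subclass factor inside
a comparison.

Two properties are worth knowing.  First, the ppm scale means the
threshold of 2 corresponds to an absolute class difference of roughly
100 ppm — abundant features pass it easily, rare ones essentially
cannot.  Second, under a global null with F features screened at
α = 0.05, about 0.05·F features pass the screen by chance and, if
abundant, usually clear the LDA threshold too; an empty result is
therefore *not* the expected null outcome once F is more than a
handful, and the pipeline's null test asserts chance-level counts, not
emptiness.

## Co-occurrence networks

Correlations default to Spearman on relative abundances: rank-based,
hence identical on raw counts and proportions within a fixed sample
set, and robust to the heavy-tailed abundance distributions of amplicon
data.  Pearson is available and the choice is recorded in the network
metadata.  A prevalence filter (present in ≥ 1/3 of the group's
samples, configurable) is mandatory-with-default: all-pairs correlation
over tens of thousands of ASVs at n ≤ 6 is statistically meaningless,
and constant taxa are excluded with a warning.  Benjamini–Hochberg
adjustment runs across all tested pairs; an edge requires
|r| > 0.6 **and** q < 0.05; vertices are taxa with at least one edge.
Networks are built per cropping system pooling both locations.

Stability metrics, pinned explicitly because the printed values they
mirror delegate their formulas to a cited method chain:

* **Complexity composite**: for each compared network, the mean over a
  configurable index set (default: vertices, edges, positive edges,
  negative edges, average degree, clustering coefficient) of
  index / max(index across the compared networks).  The densest network
  scores ≈ 1, reproducing the printed pattern; indices that are zero
  everywhere are dropped with a warning.  The composite is invariant to
  rescaling any index by a common constant.
* **Robustness**: remove ⌊pV⌋ nodes uniformly at random, with incident
  edges; remaining connectivity is the fraction of *original* nodes
  that survive and retain ≥ 1 edge, so the curve is bounded by 1 − p
  (a complete graph attains exactly 1 − p; printed robustness values at
  p = 0.5 of 0.24–0.33 are consistent with this definition).  Mean ± SD
  over seeded repetitions (default 100).
* **Vulnerability**: global efficiency E = mean over ordered pairs of
  1/d_ij (unweighted shortest paths, 1/∞ = 0); vulnerability is the
  maximum over single-node deletions of (E − E_i)/E.  Both clustering
  and efficiency/vulnerability are verified against brute-force
  enumeration on every graph with ≤ 7 nodes and on random graphs.

Implementation notes: shortest paths run through scipy's C BFS rather
than per-node Python traversals, so vulnerability on networks with a
few hundred nodes stays subsecond; node removal uses a seeded
generator.

## dbRDA

The distance matrix is embedded by PCoA (positive axes; their
eigenvalue sum is the total inertia; the dropped negative magnitude is
reported).  Environmental variables are standardized internally, so
results are invariant to affine rescaling; a condition number above
1e8 raises an error naming the most correlated pair.  The constrained
step is the least-squares projection of the coordinates onto the
environmental design followed by an SVD of the fitted values; each
constrained axis is reported as a percent of total positive inertia,
and constrained + residual inertia equals the total exactly
(projection orthogonality, tested to 1e-8).

Per-variable "explanatory degree" is the envfit-style r²: the squared
multiple correlation of the standardized variable with the first two
principal-coordinate axes, with p from permuting the variable's rows
(marginal, one variable at a time — these r² are not a partition of
inertia and may sum above the constrained percent, which is also why
published per-variable percentages can exceed the axis totals).
Because a multivariate r² has no sign, the signed correlation with
axis 1 is reported alongside.  Fewer than 99 permutations trigger a
resolution warning.

## Synthetic-data generator

The generator exists so every stage has a recovery test with known
truth.  Per domain and sample:

1. each taxon gets a base log-abundance ~ N(0, σ_log²), σ_log = 1.5 —
   a heavy-tailed profile with a realistic handful of dominant taxa;
2. only a group-dependent "active" prefix of taxa is switched on
   (active fraction 0.5 by default); a richness multiplier m for a
   system activates m× as many taxa, planting a Shannon offset whose
   analytic value is ln m in the infinite-depth, many-taxa limit (the
   lognormal evenness correction is common to both groups and cancels).
   `planted_diversity_offset` returns this analytic value; the
   finite-depth realized shift matches it within 10% at depth 30,000
   when the profile tail is moderate (σ ≲ 1), which is how the
   calibration test is configured — with σ_log = 1.5 the correction
   converges slowly in the taxon count and the identity is only
   approximate;
3. differential taxa (default 40 bacterial / 12 eukaryotic, log-fold
   ln 4) are drawn from above-median-abundance core taxa — a biomarker
   below the detection scale of the effect-size threshold would make
   the planted truth unidentifiable — and are assigned to enriched
   systems round-robin over the abundance-sorted list, so each system's
   boosted share is nearly equal and the compositional denominators
   shift together (otherwise every null taxon becomes spuriously
   differential on the relative scale);
4. correlated noise enters through a Gaussian copula: members of a
   planted module share a latent factor giving pairwise latent
   correlation ±ρ (sign mix via per-member signs); the copula-implied
   Spearman is (6/π)·arcsin(ρ/2).  Module members are taken from
   mid-abundance core slots, skipping the dominant decile: a module
   that carries a large share of the community cancels out of the
   softmax denominator and its correlation becomes nearly invisible on
   the count scale — planted on mid-abundance taxa it survives closure.
   Correlation truth is defined on the latent scale; count-scale
   correlation is attenuated by closure, depth and overdispersion;
5. counts are Dirichlet-multinomial: composition softmax(latent),
   Dirichlet-perturbed with concentration 1/θ (θ = 0.02 by default, a
   realistic amplicon overdispersion; θ = 0 gives plain multinomial),
   then a multinomial draw at the design depth — column sums equal the
   depth exactly;
6. soil variables are affine maps of the first two latent community
   gradients (left singular vectors of the centered bacterial latent
   matrix): TP and AP load on gradient 1, pH on gradient 2, EOC on
   both; the remaining eleven variables are pure-noise controls.
   Units and scales follow the field trial's reported means and SDs.

Default module sets plant the reported qualitative orderings — the
bacterial network densest under S, the eukaryotic densest under SW —
with ρ between 0.75 and 0.9, strong enough that the contrast is
detectable at the test designs' sample sizes.

**Paper-scale vs test-scale.**  The `paper` preset mirrors the field
trial (18 samples, 600/150 taxa, depth 30,000, θ = 0.02).  At that
scale the per-system networks are built from six samples and, after
BH correction over thousands of pairs, are usually empty — an honest
reflection of how underpowered all-pairs correlation is at n = 6.
Recovery tests therefore use dedicated designs that inflate what needs
inflating while keeping the planted truth fixed: `test` (48 samples,
240/120 taxa, depth 20,000, θ = 0.002), `module_recovery_design`
(one ρ = 0.9, 15-taxon module, 30 samples per system, θ = 0),
`differential_recovery_design` (the `test` design without the richness
boost, whose dilution effect would otherwise make every taxon genuinely
differential), and `complexity_ranking_design` (the `test` design at
24 samples per system).  θ ≈ 0 in the correlation-recovery designs
isolates the correlation channel from count-level overdispersion, whose
effect is tested separately.

What the generator does **not** emulate: taxonomy assignment errors,
chimeras, variable library sizes, phylogenetic structure, zero
inflation beyond what the Dirichlet-multinomial produces, and any
spatial or temporal autocorrelation between field plots.  Passing
recovery tests show the machinery detects planted structure under the
generator's assumptions; they do not certify power on real soil data.

## Calibration-test scales

Null calibrations use ≥ 500 replicates at reduced size (n = 12 for the
permutation tests, 99 permutations — the nominal 0.05 is exactly
attainable at that resolution).  The Kruskal–Wallis calibration uses
30 samples per class, where the chi-square reference for H is accurate;
at 10 per class the approximation is visibly conservative (realized
level ≈ 0.043) and a binomial band around 0.05 would flag the
approximation rather than the implementation.

## Pipeline

`run_all` executes load/simulate → soil statistics → diversity →
PERMANOVA → LEfSe → per-system networks with stability metrics → dbRDA
and writes a single JSON report plus a manifest (package version,
seeds, parameters).  Every stochastic stage's seed is derived by
hashing (global seed, stage name), so adding a stage never shifts
another stage's stream and a fixed global seed gives a byte-identical
report.  Stability metrics that are undefined on a too-small network
(vulnerability needs ≥ 3 nodes and an edge) are reported as null rather
than failing the run; a failing stage aborts with the stage name and a
partial-results marker.

## Known limitations

* Correlation networks on relative abundances inherit compositional
  artifacts; the generator makes the dominant ones visible (module
  placement, balanced differential shares) but real data offer no such
  control.  SparCC-style compositional inference is out of scope.
* Unprotected LSD letters control only per-comparison error.
* The LEfSe effect size is pinned to the published convention but not
  bit-compatible with the original tool.
* dbRDA drops negative eigenvalues; with strongly non-Euclidean
  distance matrices the discarded inertia (reported) can be
  non-negligible.
* At the field trial's own sample size (three replicates per group)
  most of the network machinery is honest but near-degenerate; the
  package reports what the data support rather than imputing structure.
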