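# Methods

This note documents the statistical machinery in `elevassembly`, the
assumptions behind it, the defaults and why they were chosen, and what the
synthetic-data validation does and does not demonstrate.

## The inference chain

The package targets a standard question in gradient microbial ecology: given
an OTU count table from samples along an elevational transect, aligned
environmental metadata, and a phylogeny, decide whether community assembly is
dominated by deterministic environmental filtering or by spatial/stochastic
processes, and how the balance shifts between the lower and higher parts of
the gradient. The chain is: α/β-diversity → ordination and permutation tests
→ richness-conserving null model and β-deviation → spatially explicit
variation partitioning of the β-deviation → path modeling of the causal
cascade climate → vegetation → soil → community.

## Diversity

**Rarefaction** subsamples each sample to a common depth without replacement
(multivariate hypergeometric); samples below the depth are dropped with a
warning. The depth is a required analysis choice with no universal default —
surveys differ too much in sequencing effort for one number to be safe — so
`AnalysisConfig.rarefaction_depth` has no preset value.

**Faith's PD** uses the rooted convention: the branch-length sum of the
minimal subtree spanning the sample's taxa *and the root*. A single-taxon
sample therefore scores its root-to-leaf path length. This matches the common
default of the standard PD implementations; the alternative (unrooted,
crown-group) convention differs by the stem path and is not offered.

**Dissimilarities.** `jaccard_binary` (presence/absence) is the default for
community-structure and null-model work, because null communities carry no
abundances. `bray_curtis` and the abundance-weighted Jaccard (Ružička,
`jaccard_abundance`) operate on relative abundances. A pair of all-zero
samples has no defined dissimilarity and raises unless the caller opts into
d = 0. Distance-decay slopes are plain OLS of similarity (1 − d) on
great-circle distance in km, untransformed on both axes, fitted separately
within each elevational section.

## Permutation tests

All tests share two conventions. Random-permutation p-values use the add-one
rule `p = (b + 1)/(m + 1)`, so p is never 0 and the floor at 999 permutations
is 0.001. Passing `n_permutations="exhaustive"` enumerates every label
permutation (identity included) and reports the exact fraction — feasible to
about n = 8 and used by the test suite to verify the samplers against
brute-force enumeration.

- **PERMANOVA**: pseudo-F from squared distances,
  SS_total = Σd²/N and SS_within = Σ_g (within-group Σd²)/n_g; identical
  communities everywhere give 0/0 and are flagged degenerate rather than
  silently reported.
- **ANOSIM**: R = (mean between-rank − mean within-rank) / (n(n−1)/4).
- **MRPP**: δ = Σ (n_g/N) · mean within-group distance; A = 1 − δ/E[δ_perm]
  with the expectation taken over the permutation distribution itself; small
  δ is extreme, so p counts permuted δ ≤ observed.
- **Mantel / partial Mantel**: correlation over off-diagonal entries, p by
  jointly permuting rows and columns of the first matrix. The partial
  variant correlates the residuals of both matrices after OLS removal of the
  conditioning matrix; a residual with (numerically) zero variance yields
  r = 0, covering the degenerate case of conditioning on the second matrix
  itself. Spearman variants pre-rank the condensed vectors; ranks are
  permutation-invariant, so ranking happens once.
- **PERMDISP**: samples are embedded by PCoA keeping both real axes
  (positive eigenvalues) and "imaginary" axes (negative eigenvalues); the
  squared distance to a group centroid subtracts the imaginary-part
  contribution (truncated at 0 if the correction overshoots). Group
  centroids, not spatial medians, are used. Significance permutes the
  distance-to-centroid values across samples — equivalent to permuting the
  null-model residuals — and is calibrated (type-I ≈ 0.05) on exchangeable
  data.
- **Kruskal–Wallis**: tie-corrected H with χ² p by default, or an exact p by
  enumerating all assignments of the pooled ranks to the group sizes. The
  post-hoc procedure is the rank-based critical difference: mean-rank
  differences against a normal quantile with Bonferroni adjustment across
  pairs. Other post-hoc conventions (Dunn with other corrections,
  Conover–Iman) exist; this one is declared, not claimed canonical.

## Null model and β-deviation

The regional species pool is every OTU observed in any sample. For each of
`n_null_iterations` (default 999) iterations and each sample, a species set
of the sample's *observed richness* is drawn without replacement from the
pool, with selection probability proportional to occupancy frequency across
samples (Raup–Crick-style assembly; `uniform` and `abundance` weightings are
selectable). Sampling uses the Gumbel top-k construction, which vectorises
and makes every iteration a pure function of `(seed, iteration)` — ensembles
are lazy, bit-for-bit reproducible, and never materialised in memory.

β-deviation is computed per sample pair from the one shared ensemble:
`z = (J_obs − mean J_null)/sd J_null` on presence/absence Jaccard
similarity, with the SD using n−1 degrees of freedom. Pairs whose null SD is
0 (forced draws) are flagged NaN and counted; for downstream ordination they
are filled at the null expectation (z = 0).

**Observed-vs-null dispersion (per site).** For each group of ≥3 samples, a
size-matched set of null communities — each member's null counterpart drawn
from an independently chosen iteration — joins the observed members; Jaccard
distances among all of them give PERMDISP distance-to-centroid values for
the observed and null groups. Because each null community is *paired* with
one observed sample (hence shares its richness), freely permuting the
distances is conservative: it destroys the pairing and inflates the
permutation variance. The test therefore flips observed/null labels within
pairs at random and recomputes centroids and F each time — exact under
within-pair exchangeability. Calibration checks (observed communities drawn
from the null process) give rejection ≈ 0.05, and strongly pH-filtered
synthetic communities are detected (observed < null dispersion, p ≤ 0.05)
in ≥95% of runs.

## Ordination and variation partitioning

**PCoA** eigendecomposes the double-centered −½D² matrix; axes are returned
for positive eigenvalues, negative eigenvalues are reported, and no
Lingoes/Cailliez correction is applied by default (the β-deviation shift
below already removes the worst offenders; PERMDISP handles negative
eigenvalues explicitly).

**NMDS** minimises Kruskal stress-1 by SMACOF iterations with monotone
(isotonic) regression; ties in the input dissimilarities use the primary
treatment (within tie blocks, disparities follow the configuration).
Defaults: 20 random starts plus a PCoA start, 300 iterations max,
convergence at stress change < 1e-7. The best configuration is centered,
PCA-rotated and scaled to unit RMS, making the output deterministic up to
axis sign.

**CCA** follows the chi-square standardization: the response
(P − rcᵀ)/√(rcᵀ) is regressed on row-weighted standardized predictors and
the fitted values SVD'd. Total inertia equals the table's χ² statistic over
its grand total (verified against the independent R/vegan implementation to
machine precision in the test suite, as are dbRDA R², PCNM eigenvalues and
PERMDISP F).

**dbRDA** regresses the positive-eigenvalue PCoA axes on standardized
predictors; R² = constrained/total inertia with the Ezekiel adjustment
1 − (1 − R²)(n − 1)/(n − p − 1). β-deviation matrices, which may be
negative, are first shifted to dissimilarities by d′ = z_max − z (larger
deviation similarity → smaller distance); the shift is recorded on the
result object. How a deviation matrix should enter a distance-based RDA is
genuinely underdetermined — alternatives (rank transforms, absolute-value
shifts) would change the fractions; this choice is the simplest
order-preserving one.

**PCNM**: the truncation threshold t is the longest edge of the minimum
spanning tree of the sample locations; distances above t are replaced by 4t
and the truncated matrix is eigendecomposed; eigenvectors with positive
eigenvalues (orthonormal) form the spatial basis. Duplicated locations are
kept as genuine zero-length MST edges.

**Forward selection** is the double-stopping rule: at each step the
candidate giving the largest adjusted-R² model enters only if its marginal
permutation p ≤ α (default 0.05, 999 permutations) *and* the cumulative
adjusted R² does not exceed the global (all-candidates) adjusted R²; a
global pre-test gates the whole procedure. Each selection step consumes an
independently seeded permutation stream, so the procedure is reproducible
step by step. One caveat is documented and handled: with strongly collinear
candidate sets, a single variable can carry an adjusted R² *above* the
global model's (redundant extra predictors drag the global adjustment
down), and the strict rule then selects nothing even when the global test
is highly significant. The optional `fallback_best=True` (used by the
acceptance pipeline) retains the single best candidate in that case,
provided its own permutation test is significant.

**Variation partitioning** computes adjR²(env), adjR²(space), adjR²(joint)
from three dbRDA fits and derives a = joint − space, c = joint − env,
b = env + space − joint, d = 1 − joint; the identity a+b+c+d = 1 holds to
1e-10 by construction. The **bootstrap fraction test** resamples samples
with replacement (`n_bootstrap` default 999), recomputes the pure fractions
a and c on each resample (degenerate resamples are redrawn, with a retry
cap), and reports the two-sided p = 2·min(P(a−c ≤ 0), P(a−c ≥ 0)). This is
this package's own definition of the test — the resampling unit is the
sample, and the statistic is the paired difference of pure fractions.

## PLS path modeling

Latents are reflective composites (mode A) estimated by the classical
alternating algorithm with the path weighting scheme for the inner estimate;
convergence when the largest outer-weight change drops below 1e-7 (300
iterations max; non-convergence raises, carrying the last delta). Path
coefficients are OLS of each endogenous latent on its predecessors over the
standardized scores; GOF = sqrt(mean communality × mean R²). Manifests are
standardized globally (not per site). Bootstrap resampling (999 by default
in the CLI) gives path standard errors and percentile CIs; a path is marked
significant when its CI excludes 0.

Two structural caveats: (i) latent orientation is sign-ambiguous — the
implementation orients each composite so its outer weights sum positive,
which stabilises blocks with concordant indicators but leaves blocks of
anti-correlated indicators (e.g. a temperature/precipitation climate block)
and NMDS-axis blocks with an arbitrary overall sign; path magnitudes are
the interpretable quantity. (ii) With single-indicator blocks the procedure
reduces exactly to classical path analysis on standardized variables, which
the test suite verifies to 1e-8.

## The synthetic gradient generator

`GradientScenario` emulates a 12-site transect at 1800–4100 m (~200 m site
spacing, 8 samples/site by default), with sites on a south–north line such
that each elevational section spans ~7 km of horizontal distance. Soil pH
follows a monotone profile from 7.23 down to 3.53 with a regime change
between 2600 and 2800 m (pH 6 separating the sections); MAP increases and
MAT/T10 decrease in elevation; carbon, nitrogen, nitrate, conductivity,
plant richness and the tree-type DBH fractions trend accordingly; ammonium
deliberately carries no trend. `noise_sd` multiplies each covariate's
natural plot-to-plot scatter (0.25 pH units, 60 mm MAP, …); 1.0 is the
default "realistic field variability", 0 gives the exactly monotone limit
the tests exploit.

Communities assemble from three separable channels, so variation-
partitioning ground truth is known: expected relative abundance ∝ lognormal
base abundance × Gaussian pH niche `exp(−(pH − opt)²/2σ²)` (optima uniform
on the observed pH range; σ = `env_filter_strength`, default 0.5 pH units)
× multiplicative vegetation affinity (lognormal per type, log-sd 0.5) ×
exponential spatial kernel `exp(−d/range)` on great-circle distance from a
random origin (range default 30 km — mild spatial structure relative to the
~15 km transect). Counts are multinomial at a uniform depth of 10,000 reads
(so default rarefaction is an identity; `depth_jitter` exercises the
non-trivial path). Trees are random Kingman-style coalescents, independent
of the niches.

What the generator does **not** emulate, and therefore what passing tests do
not show about real data: richness gradients (uniform pH optima make
richness roughly flat in pH, so the strong α-diversity–pH correlations of
real surveys are absent here); phylogenetically conserved niches; sequencing
error, compositional overdispersion beyond multinomial, or uneven library
sizes (unless jittered); and interactions among taxa. The synthetic
validation demonstrates that the estimators recover the structure they are
defined to measure, not that real mountain soils obey this generative model.

## Problem sizes and numerics

The validation suite runs its heavier checks at deliberately compact sizes
chosen to keep Monte Carlo error well inside the asserted bands: null-model
self-consistency at 100 runs × 999 iterations on 16-sample/150-OTU tables;
filtering detection at 100 seeded scenarios of 2 sites × 8 samples; type-I
calibration at 500 simulations × 199 permutations at n = 12; PLS recovery
at 100 seeds × n = 500. Symmetric matrices are validated to 1e-12 and
symmetrised before use; eigenvalues below 1e-10 of the spectral radius are
treated as zero; permutation-statistic comparisons use a 1e-12 slack so
ties count as exceedances; all stochastic code takes an explicit integer
seed and derives any sub-streams through `SeedSequence`, and result objects
record the seed they were produced with.
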