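# Methods

`cladepath` implements a comparative pipeline for asking what drives the
diversification of a clade of host-specialized organisms (its motivating
case: Nearctic aphids and their host plants): do clades become species-rich
because host-use divergence drives speciation, or because host-use
divergence raises the ecological limits on richness while speciation is
driven by divergence in non-host (environmental) niche axes?  The pipeline
has four stages: niche construction, tip-level rate statistics,
phylogenetic confirmatory path analysis, and synthetic data generation for
validation.  This note records the models, the defaults, and the design
choices made where the methodology left the design open.

## Niche construction

**Host-use space.** Host use enters as a binary species × plant-family
incidence matrix.  Pairwise Jaccard distances, d(i,j) = 1 − |A∩B|/|A∪B|
over host-family sets, are embedded by classical scaling (principal
coordinates): the matrix −D²/2 is double-centered and eigendecomposed.
Axes with non-positive eigenvalues are discarded — no Cailliez or Lingoes
correction — and variance fractions are reported over the positive
eigenvalues only.  The first two coordinates give each species an address
in host-use space.  Host breadth is Shannon's H = −Σ pᵢ ln pᵢ (nats) over
the families a species uses; by default each used family gets equal weight
(incidence), with usage counts supported where available.

**Environmental space.** Occurrence records (species, lon, lat) mask
gridded environmental layers: each point is assigned the value of its
containing cell; species with fewer than 10 records are excluded (an
inclusive threshold, the sampling level at which distribution estimates
become usable).  Per variable and species the pipeline reports the mean
and the 25–75% interquantile range (type-7 linear-interpolation quantiles;
IQR rather than min–max to resist outliers).  Monthly layers are
annualized before extraction — mean for intensive variables, sum for
fluxes — and categorical layers (soil class, land cover) are summarized as
the modal class plus class richness, since a mean of class codes is
meaningless.  The resulting feature matrix is reduced by PCA on the
correlation matrix (variables standardized, because units are
incommensurable); the first two component scores are the environmental
niche coordinates.  Ordination axes are sign-ambiguous; the sign is fixed
so the largest-magnitude score on each axis is positive.

Grids are plain-text matrices with a JSON sidecar (bounding box, cell
size); row 0 is the northern edge.  5 arc-min (1/12°) is the default cell
size the defaults emulate.

## Tip-level rate statistics

**DR.** The speciation-rate index of a tip is the inverse of an
equal-splits weighted sum of the branch lengths on its root path:
DR_i = (Σ_j l_j · 2^{−(j−1)})^{−1}, j = 1 at the tip's own branch.  Units
are inverse branch-length units.

**Ancestral states.** Internal-node states of a continuous trait are the
maximum-likelihood Brownian-motion estimates.  The root is the GLS mean
(1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x with V the BM tip covariance (shared root-path length);
other nodes are the conditional expectations given the tips, which
coincide with the GLS root estimate of the tree re-rooted at each node.
Estimates are computed by one Cholesky solve plus a preorder recursion for
the node–tip covariances, O(n²) overall.  Zero-length pendant edges that
make V singular get a ridge of 10⁻⁸ × tree height, with a warning.

**TR.** The trait-rate analogue of DR: for each tip, the sum of
between-node differences in reconstructed states along its root path, with
the tip's own observed value as the terminal child state.  Differences are
absolute by default — a rate index should be non-negative, and signed
differences largely cancel along a path — with a `signed` flag for
sensitivity analysis.  The default is the raw (unweighted, un-normalized)
sum; optional variants apply DR-style 2^{−(j−1)} down-weighting
(`dr_weighting`) or divide by root-path length (`per_unit_depth`).  The
within-package validation of TR as a rate index uses the per-unit-depth
variant: in trees where one clade's BM rate is ×10, within-clade mean TR
per unit depth exceeds the outside mean in ≥95% of simulations.

**PIC.** Felsenstein's phylogenetic independent contrasts, with the
standard branch-length adjustment v_parent += v_L·v_R/(v_L+v_R).
Polytomies are resolved in input order with zero-length internal branches
(warned).  Under BM with rate σ², contrasts are iid N(0, σ²); this
calibration is tested directly.

## Confirmatory path analysis

A causal hypothesis is a DAG over named variables (text format: `A -> B`
lines, plus `A ~~ B` for a free correlation between exogenous variables).
Its testable content is the d-separation basis set: one claim
X ⟂ Y | pa(X) ∪ pa(Y) per non-adjacent pair, ordered by causal order.
Each claim is tested as the partial regression of Y on X given the
conditioning set, in one of two modes:

* `gls-bm` — GLS with the BM tip covariance of a supplied tree, for raw
  cross-species (or cross-genus) data;
* `contrasts-ols` — OLS **through the origin** on independent contrasts
  (contrasts have no defined intercept);
* `ols` — ordinary iid regression, for data with no phylogenetic
  structure.

Claim p-values combine into Fisher's C = −2 Σ ln pᵢ, chi-square with 2k df
under the hypothesized DAG; a model p below 0.05 is flagged as indicating a
missing causal relationship.  Competing DAGs are ranked by
CICc = C + 2qn/(n − q − 1) with q = edges + exogenous variances and
correlations (the Shipley convention).  p-values of exactly 0 are clamped
at 1e-300 with a warning.

The same DAG is also fitted as a recursive linear-Gaussian path model:
each endogenous variable is regressed on its parents (same mode rules),
on variables scaled to unit variance so coefficients are standardized mean
differences (SMD); standard errors come from the per-equation information
matrix (no bootstrap).  The system log-likelihood gives
AIC = −2ℓ + 2k with k counting edges, all variances, exogenous
correlations, and (when estimated) means.  Goodness of fit is the ML
discrepancy between the observed covariance S (phylogenetically corrected
in GLS mode) and the implied covariance Σ = (I−B)⁻¹Ψ(I−B)⁻ᵀ:
T = n·F_ML, chi-square with p(p+1)/2 − t df; a just-identified model has
df = 0 and T = 0 by construction.

Effects decompose by path tracing: direct = the edge coefficient, indirect
= the sum over directed paths of length ≥ 2 of the product of edge
coefficients, total = direct + indirect.  All simple paths are enumerated
exhaustively (the DAGs here have ≤ 6 nodes).

**Normalization.** Because niche variables and rate statistics are heavily
skewed, variables are passed through a rank-based ordered-quantile
transform, Φ⁻¹((rank − ½)/n), before modeling (the `QuantileNormalizer`
transformer; strictly monotone, ties preserved).  It can be disabled in
the run config.

**Multi-axis constructs.** Host-use and environmental niche each enter the
speciation models as two ordination axes.  A construct-level edge expands
axis-wise (axis 1 → axis 1, axis 2 → axis 2; a construct → scalar edge
expands to one edge per axis), and the reported construct-level edge value
is the sum of the expanded standardized coefficients.  This "combined
effect of the first two components" convention is an interpretive choice;
the axis-level coefficients are always written alongside.

## Pipeline assembly

**Richness mode.** The tree is collapsed to one tip per genus.  A genus's
core clade is its largest pure clade (the deepest node whose descendant
tips all belong to the genus); members outside the core clade are treated
as phylogenetically misplaced and dropped from both the collapsed tree and
the richness tallies.  The representative tip is the retained congener
with the most occurrence records (ties alphabetical) and keeps its root
distance exactly.  Genus variables: richness (supplied), host-use
diversity = Shannon index over the members' pooled family incidences, and
environmental diversity = total variance (sum over PC axes) of member
scores.  Singleton genera score 0 on both diversity measures — one species
carries no within-genus diversity.  Candidate DAGs (default: direct +
indirect vs indirect-only effect of environmental diversity on richness)
are fitted in `gls-bm` mode on the genus tree and ranked by CICc.

**Speciation mode.** DR per tip; TR per niche trait (host-use axes,
environmental axes, host breadth); PICs of all of them on the
binary-resolved tree; normalization; then two model families in
`contrasts-ols` mode — with and without the host-breadth rate — each
ranked by AIC (CICc is also reported), with construct-level effect
decomposition of the best model.

Reports are plain TSV + JSON, deterministic given config and inputs, with
a structured audit log (operation, input hashes) per stage.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
at the study's scale; its defaults are fixed once and are not tuning
knobs.

* **Trees**: Gillespie birth–death runs conditioned by rejection on the
  extant tip count (default 371 tips, birth 1.0, death 0.25 — a moderate
  extinction fraction); a final shared waiting time is added to all
  pendant branches, so extant trees are ultrametric in real time.
* **Traits**: BM evolved edge-by-edge, increments N(0, σ²l), with rate
  multipliers inside clades anchored by tip sets (MRCA subtree).
* **Host incidence**: per family, a latent score mixes a standardized
  Brownian component (tree with pendant branches collapsed, so cherry
  sisters share it exactly) with iid noise, z = √c·B + √(1−c)·ε; c is the
  phylogenetic clustering strength (default 0.6), thresholded at the
  prevalence quantile (default 0.25); every species keeps ≥ 1 family.
* **Environment**: Gaussian random fields (kernel-smoothed white noise,
  default smoothing length 4 cells) on a 40×60 grid at 1/12° emulating a
  Nearctic window; range centroids evolve by BM on the tree; ≥ 10
  occurrences per species (default mean 40), scattered around the
  centroid and snapped to cell centers so extraction tests are exact.
* **SEM data**: recursive linear-Gaussian systems sampled in topological
  order, residual variances solved so every variable has exactly unit
  population variance (supplied coefficients are therefore the population
  standardized coefficients); infeasible combinations raise.
* **Rate worlds** (end-to-end validation): DR is a deterministic
  functional of the tree, so a causal system *on* rate statistics cannot
  be imposed after the fact.  Instead, three variables (environmental
  rate, host-use rate, a speciation-rate proxy) evolve as coupled
  Brownian motions whose per-edge increments satisfy the chain
  env → host → speciation; a linear structural system among BM increments
  is inherited exactly by the independent contrasts, so the generating
  coefficients are the population values at the contrast level.

Randomness follows a single root seed split into named substreams
(SeedSequence spawn keys from a CRC of the component name), so adding a
generator never perturbs another's stream and all outputs are
bit-reproducible.

What the generator does **not** emulate: sampling biases in occurrence
records, taxonomic name noise, trait-dependent diversification (no SSE
processes), non-Brownian trait evolution, and real spatial structure
(coastlines, climate gradients).  Passing tests therefore demonstrate the
correctness and calibration of the machinery under its own assumptions,
not robustness to the ways real data violate them.

## Numerical choices and edge cases

* Newick: branch lengths required on all non-root edges; duplicate tips,
  negative lengths and malformed input raise; bracketed (NHX) comments
  are stripped with a warning; serialization keeps 12 significant digits.
* Zero-length branches are permitted but warned; GLS matrices that would
  be singular get the ε-ridge described above.
* PCoA/PCA axis signs: largest-magnitude loading positive.
* Constant feature columns are dropped from PCA with a warning; constant
  model variables raise a degenerate-variable error before fitting.
* Quantiles: type-7 (linear interpolation), NumPy's default.
* Polytomies: resolved in input order with zero-length branches for PIC.
* Model comparison requires identical n across fits; ranking is stable
  under ties.

## Validation scale

The shipped validation suite runs at desk scale: oracle agreement on
100-tree batches (trees up to ~130 tips), contrast calibration on 500
replicates of 200-tip trees, TR rate-shift recovery on 200 replicates,
C-test type-I error on 1000 null simulations at n = 200, and end-to-end
model selection on 100 replicates of 300-tip worlds.  These sizes were
chosen to make Monte-Carlo error small relative to the acceptance bands
while keeping a full run in minutes.

## Known limitations

* BM is the only trait and residual-correlation model (no OU, no Pagel's
  λ); the GLS mode is deliberately BM-only.
* TR's absolute-difference sum estimates reconstructed, hence shrunken,
  path change; it is a relative index, not an unbiased estimator of σ².
* The C-statistic test treats basis-set p-values as independent; this is
  an approximation (its empirical size is checked by simulation).
* Genus "diversity" composites are operationalized choices (pooled
  Shannon; PC-score variance); alternatives (mean pairwise Jaccard,
  convex-hull area) would be drop-in replacements.
* GeoTIFF ingestion is not implemented; grids are plain-text + JSON
  sidecar behind the same contract.
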