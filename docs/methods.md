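# Methods

## Scope and model

phylospat analyses plot-survey community data in two stages. The first
quantifies phylogenetic community structure: for each site's species set it
computes Faith's PD, mean pairwise distance (MPD) and mean nearest-taxon
distance (MNTD) on a rooted, branch-length-bearing phylogeny, and
standardizes each against a randomization null to give PDI, NRI and NTI.
The second stage relates species richness and the three SES indices to
site-level environment (elevation, slope, aspect, a five-level bedrock
factor, a bioclimatic block) with group contrasts, stepwise-AIC Gaussian
GLMs, and maximum-likelihood spatial-lag regression on k-nearest-neighbour
weights.

## Metric conventions

- **PD is root-inclusive by default**: the spanning subtree is connected to
  the tree root, so a single species contributes its full root-to-tip path.
  This matches the convention of the picante lineage (`pd(..., include.root
  = TRUE)`), against which the implementation is cross-checked in the test
  suite. The crown-only variant is available via `include_root=False`; which
  convention a given analysis used is worth stating explicitly, since the
  two differ by the root→MRCA path length.
- **MPD/MNTD are presence/absence (unweighted)**. Abundance weighting is
  deliberately not implemented: the analyses this package supports are
  occurrence-based, and a silent abundance option would invite mixed-mode
  mistakes.
- Branch lengths of exactly zero are accepted (grafted polytomies produce
  them); negative lengths and missing lengths are parse errors. Distances
  are computed in double precision; test comparisons use 1e-9 absolute
  tolerance.

## The null model

The null is a **taxa-label randomization**: each of the `n_null` (default
999) draws is a uniformly random species set of the observed richness taken
from the species pool, equivalent to shuffling tip labels restricted to the
pool. The pool defaults to all tree tips; analyses that want the union of
observed communities can pass it explicitly. Frequency-preserving and
independent-swap nulls are out of scope. The chosen scheme is recorded in
every output's metadata header rather than asserted as the only defensible
choice.

Sign conventions: PDI is the plain SES of PD; NRI and NTI carry a leading
minus, so positive values indicate phylogenetic clustering. `classify_structure`
maps NRI/NTI sign directly to clustered/overdispersed; for PDI it inverts
the sign first (less diversity than expected = clustering). A degenerate
null (sd = 0, e.g. the community equals the pool) yields an explicit
`undefined` flag, never ±inf, and propagates into the regression stage as a
missing response; SAR then runs on complete cases with weights rebuilt on
the retained sites.

Reproducibility: each site's null stream derives from
`SeedSequence(master_seed, spawn_key=(site_index,))`, so results are
bit-identical regardless of evaluation order, and rerunning the pipeline
with the same seed reproduces every output CSV byte for byte.

## Preprocessing

- **Hellinger transform**: entry (s, j) → √(x<sub>sj</sub>/rowsum<sub>s</sub>);
  each transformed row has unit sum of squares. Empty sites are an error
  naming the site. Species richness used as a regression response is always
  the raw occurrence row sum — the transform never alters it.
- **Range normalization** (x − min)/(max − min) is applied to quantitative
  predictors; constant vectors are rejected rather than mapped arbitrarily.
- **Collinearity screen**: greedy scan in declared column order (BIO index
  ascending), dropping any later column whose correlation with a retained
  column exceeds 0.95. The default compares |r| — catching strong negative
  collinearity too — with a signed-r flag available, since either reading of
  "correlation greater than 0.95" is defensible; the choice is logged with
  every dropped pair. Zero-variance columns are removed with a warning
  before any correlation is computed, and the postcondition (all retained
  pairs ≤ threshold) is re-checked.
- **Aspect** enters models as supplied (degrees). A northness/eastness
  cosine transform exists upstream of none of the defaults; if circularity
  matters for a given dataset, transform before loading.

## Regression stage

Group contrasts are Welch unequal-variance t-tests (two-sided, with
Welch–Satterthwaite df); a pooled-variance flag exists because published
analyses often do not say which was used. Raw pairwise p-values are
reported without multiplicity correction, mirroring common practice in the
descriptive figures this stage reproduces; stars follow * p<0.05,
** p<0.01, *** p<0.001.

The stepwise search fits Gaussian identity-link models, evaluating at each
step every single-term addition (and, with `direction="both"`, deletion),
taking the move with the largest AIC decrease and stopping at a local
minimum. The bedrock factor moves as one block of dummy columns with
**granite as the reference level**. AIC is computed as 2k − 2 logLik with k
counting the error variance (the R `AIC()` convention), so a parameter with
zero likelihood gain costs exactly 2. AIC ties are broken by declared
candidate order and noted in the selection log; perfectly collinear
candidates are excluded up front with a warning. All four responses (SR,
NRI, NTI, PDI) are fit in the same Gaussian framework; richness is treated
as continuous after upstream normalization rather than Poisson-modelled.

## Spatial stage

Weights default to k-nearest-neighbour (k = 4), row-standardized, with
great-circle distances for lon/lat coordinates (spherical approximation,
auto-detected from column names) and Euclidean for planar; distance ties,
including duplicate coordinates (warned), break by site order. The scheme is
unreported in many published analyses, so it is always written into output
metadata.

Moran's I uses the randomization-moment normal approximation; its
expectation is −1/(n−1).

The SAR **lag** model (I − ρW)y = Xβ + ε is estimated by maximizing the
concentrated log-likelihood over ρ, with log|I − ρW| from the eigenvalues
of W (complex pairs handled via moduli) and ρ confined to
(1/λ<sub>min</sub>, 1/λ<sub>max</sub>) of the real eigenvalue range. A
spatial-**error** variant (spatial filtering of both y and X) is available
by flag; neither is asserted as "the" SAR, since published descriptions
often do not distinguish them. With an all-zero W the fit reduces to OLS
exactly. Coefficient standard errors are conditional on ρ̂
(σ²(X′X)<sup>−1</sup>); ρ's own standard error comes from the profile
likelihood curvature. The optimizer tolerance is 1e-9 on ρ.

"Percent of variation explained" is the Nagelkerke pseudo-R²
1 − exp((2/n)(logL₀ − logL₁)) against the **intercept-only OLS null**,
clamped to [0, 1] with a warning if the model likelihood falls below the
null; the squared observed–fitted correlation is available by flag. The two
variants can differ noticeably, so reported percentages should name the
convention.

## Synthetic data: what it emulates and what it does not

The generator mirrors the scale of a subtropical montane survey: 75 plots,
a 594-species pool, five bedrock classes, elevation 0–869.7 m, and a
bioclimate block in CHELSA-style units. Specifics:

- **Yule trees**: pure-birth with exponential waiting times; with birth rate
  b the expected total branch length is n/b, used as a distributional check.
- **Assembly regimes**: filtering includes species with probability
  ∝ exp(−d(focal, ·)/τ) around a random focal tip; repulsion selects
  sequentially with probability ∝ distance to the nearest already-selected
  species; neutral draws uniform subsets. The kernels are the minimal
  mechanisms producing clustered/overdispersed signatures — no claim is made
  that real assembly follows an exponential kernel. Default τ is a quarter
  of the median cophenetic distance, which produces strong but not
  degenerate clustering.
- **Landscapes**: a single-peak elevation surface inside a ~6 × 11 km
  lon/lat bounding box, a Voronoi mosaic of five contiguous bedrock patches,
  climate columns driven by thermal (elevation) and moisture (coastal
  gradient) latent factors with an engineered near-duplicate pair
  (|r| > 0.95, so the collinearity screen always has work to do), and a
  response y = (I − ρW)<sup>−1</sup>(Xβ + ε) with defaults ρ = 0.4, noise
  sd 1, elevation and dry-month precipitation effects, and bedrock offsets.
  Per-site richness follows a mid-to-high-elevation maximum with bedrock
  offsets, capped at 60 % of the pool so the null never degenerates.

What passing the synthetic tests does **not** show: robustness to
phylogenetic uncertainty, to detection error in occurrences, to non-Gaussian
richness noise, or to climate surfaces rougher than the two-factor
construction; real bedrock mosaics are not Voronoi cells; and the assembly
model has no abundance dynamics or trait evolution.

## Calibration studies (evaluation module)

The quantities in `scripts/acceptance.py` are computed by
`phylospat.evaluation` at these problem sizes, chosen to give stable
statistics at interactive runtimes: 100 random trees (≤ 12 tips) for exact
oracle agreement; 500 neutral sites × 999 nulls for SES calibration
(expected mean ≈ 0, sd ≈ 1); 200 sites per assembly regime; 500 iid draws
at n = 100 for Moran's I; 100 landscapes at n = 200 for ρ recovery; 20
replicates at n = 150 for the ρ = 0 OLS limit (slope coefficients compared;
the intercept absorbs ρ̂ × mean lagged response and reflects ρ's sampling
noise, not slope disagreement); 100 runs for stepwise retention at a 5-sd
effect.

## Known limitations

- Dense n × n matrices throughout the spatial stage: fine to a few thousand
  sites, not intended for gridded rasters.
- The taxa-label null is the only null; conclusions sensitive to occupancy
  frequency structure need an independent check.
- SAR inference is asymptotic (z-tests); no small-sample or heteroskedastic
  corrections.
- The newick reader ignores internal node labels and requires branch
  lengths on every non-root edge.
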