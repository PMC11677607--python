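# phylospat

Community phylogenetic structure and spatially explicit diversity regression,
for ecologists analysing plot-survey data: a site × species occurrence table,
a dated phylogeny of the species pool, per-site environment (topography,
bedrock geology, bioclimate), and site coordinates. The package quantifies
whether each community is phylogenetically clustered or overdispersed —
evidence for environmental filtering vs. competitive exclusion in community
assembly — and then models species richness and phylogenetic structure as
functions of environment while accounting for spatial autocorrelation among
neighbouring plots.

## The statistics at the core

**Diversity metrics.** For a community with species set *S* on a phylogeny
with cophenetic distances *d(i, j)*:

- Faith's PD: total branch length of the subtree spanning *S* (root-inclusive
  by default, crown-only by flag);
- MPD: mean of *d(i, j)* over all unordered pairs in *S*;
- MNTD: mean over *i* ∈ *S* of min<sub>j≠i</sub> *d(i, j)*.

**Standardized effect sizes.** Each metric is standardized against a
taxa-label randomization null — 999 random species sets of the same richness
drawn from the pool:

- PDI = (PD<sub>obs</sub> − PD<sub>rand</sub>) / sd(PD<sub>rand</sub>)
- NRI = −(MPD<sub>obs</sub> − MPD<sub>rand</sub>) / sd(MPD<sub>rand</sub>)
- NTI = −(MNTD<sub>obs</sub> − MNTD<sub>rand</sub>) / sd(MNTD<sub>rand</sub>)

Positive NRI/NTI means the community's species are more closely related than
the null expects (phylogenetic clustering); negative means overdispersion.

**Regression stage.** The community table is Hellinger-transformed,
quantitative predictors are scaled by (x − min)/(max − min), the
collinear climate block is screened at |r| > 0.95, responses (SR, NRI, NTI,
PDI) are compared across bedrock classes with Welch t-tests, modelled by
stepwise-AIC Gaussian GLM, and refit with the maximum-likelihood spatial lag
model

y = ρWy + Xβ + ε

on row-standardized k-nearest-neighbour weights W, reporting ρ, coefficient
z-tests, AIC, Nagelkerke pseudo-R² = 1 − exp((2/n)(logL₀ − logL₁)), and
residual Moran's I.

A fully seeded synthetic-data generator (Yule trees; neutral / filtering /
repulsion community assembly; landscapes with an elevation gradient, a
five-level contiguous bedrock mosaic, a deliberately collinear climate block
and a spatial-lag response) makes every stage testable end to end.

## Worked example

```python
import phylospat as ps

tree = ps.parse_newick("((A:1,B:1):1,C:2);")
D = ps.cophenetic_matrix(tree)
print(ps.faith_pd(tree, ["A", "B"]))   # 3.0  (branches A, B + stem to root)
print(ps.mpd(D, ["A", "B", "C"]))      # 3.3333...  = (2+4+4)/3
print(ps.mntd(D, ["A", "B", "C"]))     # 2.6667...  = (2+2+4)/3
```

SES indices on a simulated filtering-assembled community
(`python examples/02_null_models_ses.py`):

```
--- filtering community (10 species) ---
NRI: observed MPD=2.751, null 5.482 +/- 0.397, SES=+6.88 -> clustered
NTI: observed MNTD=0.935, null 2.362 +/- 0.454, SES=+3.14 -> clustered
PDI: observed PD=10.940, null 19.293 +/- 1.518, SES=-5.50 -> clustered
```

The community holds far less pairwise distance and branch length than a
random draw of 10 species from the pool — the signature of environmental
filtering. Spatial regression (`python examples/04_spatial_regression.py`)
on a landscape simulated with ρ = 0.6:

```
OLS residual Moran's I = +0.2032 (expectation -0.0050, p = 8.08e-06)
SAR lag: rho_hat = 0.537 (true 0.6), AIC = 586.05, Nagelkerke pseudo-R2 = 0.962
SAR residual Moran's I = -0.0238 (p = 0.688)
```

OLS leaves strong residual autocorrelation; the lag term absorbs it and the
ρ estimate lands near the generating value. Each script in `examples/`
demonstrates one capability; `examples/05_full_pipeline.py` runs the whole
workflow on a 75-site, 594-species synthetic survey.

## Command line

```bash
phylospat simulate --n-species 594 --n-sites 75 --seed 1 --output-dir data/
phylospat all --tree-path data/tree.nwk --community-path data/community.csv \
    --environment-path data/environment.csv --coordinates-path data/coordinates.csv \
    --n-null 999 --seed 1 --output-dir results/
```

Subcommands `validate`, `diversity`, `regress` and `spatial` expose the
individual stages; every output CSV carries a `#`-prefixed metadata header
(seed, null size, weights scheme, version) sufficient to reproduce it.

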