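# Methods

This note documents the models implemented in `urbanscale`, the design
choices made where the methodology was genuinely open, what the synthetic
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Study design being emulated

The pipeline targets breeding-bird point-count surveys in a
forest-dominated region: locations at least 400 m apart, each surrounded
by >50% forest within 0.2 km (so that detected species plausibly breed in
forest), analyzed within circular landscapes of 10 radii spanning
0.2–16 km. Landscapes whose disc extends past the grid border are dropped.
Species are single-visit presence/absence records; abundance is not
modeled.

## Synthetic landscape generator

Land cover is a thresholded-Gaussian-random-field construction. An
urbanization field — Gaussian kernels around randomly placed centers whose
sizes vary log-uniformly over a factor of five (towns down to hamlets),
plus fine-scale autocorrelated noise — ranks cells from rural to urban.
For gradient strength `s ∈ (0, 1]`, the forest fraction equals the
configured target (default 0.58, a predominantly forested state) and the
remainder is split developed : agriculture : other ≈ 0.55 s : the rest :
0.05. Developed cells take the four NLCD intensity classes by urban-field
quantile; population and housing density increase monotonically (with
log-normal noise) along the same field, so the six urbanization variables
share one dominant PCA axis, as in real census/NLCD data. `s = 0` yields
an all-forest landscape.

The multi-size urban centers are a deliberate design point: with a single
smooth urban gradient, urbanization scores at adjacent radii correlate
at ~0.95 and the scale of effect is unidentifiable by construction. With
settlement structure at several spatial scales (also the realistic case),
scores at radii differing by 2× correlate at ~0.85–0.9 and scale recovery
becomes a well-posed classification task.

What the generator does **not** emulate: road-network placement of count
points, real coordinate reference systems, observer-specific detection
error beyond a categorical covariate, spatial autocorrelation of
occurrence beyond what the landscape induces, and abundance. Passing
recovery tests therefore demonstrates the estimator's correctness under
the stated sampling model, not robustness to those real-data features.

## Occurrence truth model

Detection probability is
`expit(α + β_true · U(s_true) + Σ γ_j z_j)` with `U` the urbanization PCA
score at the species' true radius, standardized across locations
(`β_true` is log-odds per SD), and `z_j` standardized nuisance covariates.
Draws are independent Bernoulli; a detection table stores presence with
`detected = (count ≥ 1)`.

## Landscape metrics

- **Buffer membership**: a cell belongs if its center lies strictly within
  the radius (Euclidean). A disc smaller than the grid spacing returns the
  single containing cell. Discs leaving the grid are flagged incomplete
  and excluded downstream.
- **Patch density**: 8-neighbor connected components of the class within
  the buffer, per 100 ha of buffer area.
- **Clumpiness (CLUMPY)**: from rook adjacencies counted only between
  cell pairs both inside the buffer (double-count convention),
  `G = g_ii / (g_i· − min e)` with `min e` the minimum perimeter of a
  maximally compact arrangement of the class' area;
  `CLUMPY = (G − P)/P` when `G < P` and `P < 0.5`, else `(G − P)/(1 − P)`.
  Conventions chosen to match FRAGSTATS defaults: 8-neighbor rule for
  patch delineation, rook adjacencies for CLUMPY, and no border padding.
  Degenerate guards: `P = 1` returns 1; when `g_i· − min e ≤ 0` (tiny
  classes) `G` falls back to `g_ii / g_i·`; `G` is capped at 1.
- **Shannon diversity**: `H = −Σ p_k ln p_k` over classes present.
- **Urbanization PCA**: correlation-matrix PCA (the six variables have
  incommensurate units); eigenvalue > 1 retention with a small (1e−9)
  numerical tolerance; if nothing qualifies the first component is kept
  with a warning; each retained component is sign-oriented to correlate
  non-negatively with housing density so "higher = more urban" is stable.
  Developed-class proportions that are constant across all buffers at a
  radius (common at 0.2 km under the forest rule) are dropped from the
  PCA input with a log entry.

## Forest-dependency classification

Locations are ordered by ascending forest amount; the species' cumulative
count fraction is compared with the cumulative forest fraction and the
maximum absolute gap D (evaluated at distinct forest values, making D
invariant to tie relabeling) is the test statistic. Because counts act as
weights rather than i.i.d. draws, the null distribution comes from seeded
permutations of counts over locations (default 1000) rather than the
asymptotic Kolmogorov–Smirnov law. Per radius, a species votes
forest-dependent when the test does not reject or when it rejects with
counts concentrated in the most-forested landscapes; the final label is
the majority vote across radii with ties going to forest-dependent.
Species below 30 occupied locations, or carrying exclusion flags (hybrid,
irregular breeder, raptor, waterfowl, nocturnal), are dropped first. The
combination rule across radii and the permutation null are reconstructions
of a procedure whose exact form is not published; both are configurable.

## Stage 1 conventions

- **Partial SD**: `s*_j = s_j √(1/VIF_j) √((n−1)/(n−p))` with
  `VIF_j = 1/(1 − R²_j)` from regressing predictor j on the others.
  Columns are divided by `s*_j` and then centered/scaled to unit variance;
  the stored parameters invert the transform exactly.
- **Categorical covariates** (observer, year, dominant habitat) enter as
  treatment-coded indicator blocks included or excluded from subsets as a
  unit and exempt from partial-SD division (defined for continuous
  predictors only).
- **AIC**, not AICc: `−2ℓ + 2K`, K counting the intercept; sample sizes
  here are far above K.
- **Complete separation**: flagged fits are dropped from the candidate set
  (their ML optimum is at infinity, so their AIC is not meaningful) with a
  log entry.
- **Averaging set**: ΔAIC ≤ 2, weights renormalized over that set (the
  best model always qualifies). Full averaging contributes β = 0 for
  subsets lacking the urbanization term.
- **Unimodality**: the weighted Gaussian KDE (Silverman bandwidth) of the
  candidate coefficients must have a single local maximum; sets of ≤ 2
  models are unimodal by definition. Non-unimodal (species, radius) pairs
  are excluded from scale selection.
- **Collinearity**: pairwise predictor |r| ≥ 0.70 warns but does not
  exclude — the reference analysis reports its correlations stayed below
  that threshold without defining a removal rule.
- **Scale of effect**: argmax |β̄| over usable radii, ties to the smallest
  radius.
- The second PCA component, where retained, is a candidate covariate but
  never the averaged target.

## Stage 2 conventions

- Effect sizes are weighted by 1/SE²; scale-of-effect responses are
  modeled unweighted on the km scale (no SE accompanies a selected scale)
  and as a continuous Gaussian response even though scales come from 10
  discrete radii — an ordinal model is out of scope.
- Traits are transformed exactly like stage-1 predictors (partial SD, then
  standardization); binary traits included.
- AIC counts K = coefficients + intercept + error SD, so an
  intercept-only model has K = 2 and a one-trait model K = 3, matching the
  published tables' convention.
- Two trait groups handle missingness without imputation: screened traits
  (univariate adjusted R² > 0) on complete-case species, and traits with
  values for every species. A trait appearing in both groups' ΔAIC ≤ 2
  best-model sets reports its larger-magnitude averaged coefficient.
- **PGLS screen**: `V(λ)` scales the off-diagonal Brownian covariance
  (diagonal unchanged); λ is estimated by ML on [0, 1] (bounded
  optimization plus explicit endpoint checks) with σ² profiled out; the
  LRT against λ = 0 uses the boundary-corrected ½χ²₁ p-value. On a star
  phylogeny λ is unidentified and reported as 0. The screen gates
  nothing: if signal is detected the run warns and proceeds
  non-phylogenetically, listing the affected traits.
- The multi-tree replication of the reference analysis (random backbone
  trees) reduces to a single user-supplied Newick; loop externally for
  multiple trees.

## Trait and phylogeny generator

Yule trees are simulated directly (exponential waiting times, uniform
lineage splits), guaranteeing positive branch lengths. Traits evolve as
unit-variance λ-scaled Brownian characters; binary traits threshold the
latent at the prevalence quantile. True coefficients are
`β_true = β₀ + Σ w_t z_t + ε` with `z_t` the *observed* standardized trait
(so stated weights are per-SD effects recoverable by the trait models) and
ε Gaussian; true scales are built the same way on a log₂-km axis and
snapped to the nearest configured radius. Missing values are punched in
MCAR per trait after the truth is computed. Defaults: β₀ = −0.36 (the
cross-species mean of the reference table), scale center 1.5 km, noise SD
0.1.

## Recovery experiments (problem sizes)

- Stage 1: one landscape (32 × 32 km, 80 m cells), 2000 locations, 50
  species with β_true = −1 at radii {0.5, 1, 2} km; nuisance effects on
  elevation (−0.3/SD) and the land-use-change flag (+0.2) — covariates
  that are not scale-entangled urbanization proxies, because the target of
  the experiment is the urbanization term's own radius. Measured:
  fraction of species with the exact true scale selected, and fraction
  whose averaged coefficient at the true radius lies within 2
  unconditional SEs of −1.
- Stage 2: 50 replicates × 60 species, six traits, one planted +0.5/SD
  granivory effect (noise SD 0.1, response SE 0.1); and an all-null twin
  measuring per-trait 95%-interval coverage of zero.
- λ: 25 replicates of 64-tip Yule trees under λ = 1 Brownian responses and
  under i.i.d. responses.

These sizes keep the full suite within a few minutes on one CPU while
leaving comfortable Monte-Carlo margins around the pass thresholds.

## Known limitations

- The forest-dependency statistic is a reconstruction; its permutation
  null is not exchangeable if counts are spatially autocorrelated beyond
  the landscape covariates.
- Overlapping landscapes at large radii induce dependence between
  locations that stage 1 ignores (as does the reference analysis, citing
  evidence the impact is small).
- The KDE unimodality check is bandwidth-dependent; pathological candidate
  sets near the ΔAIC = 2 boundary can flip the flag.
- Range masks enter as per-species allowed-location sets; occupancy-model
  range estimation itself is out of scope.
- GeoTIFF output is plain single-band TIFF with grid metadata in the image
  description; no CRS is attached by design.
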