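# urbanscale

Multi-scale, trait-mediated analysis of species occurrence responses to
urbanization intensity.

## The problem

How strongly does urbanization affect where a forest bird species occurs,
at what landscape scale does that effect act, and which species traits
predict both? `urbanscale` implements the full two-stage inference pipeline
used to answer these questions from point-count data, together with a
synthetic-data generator that reproduces the study design with known
ground truth, so every stage is testable by parameter recovery. It is
aimed at landscape ecologists and biostatisticians working on
"scale of effect" questions.

## The method

**Urbanization index.** For every count location and every buffer radius
(0.2–16 km by default), six variables — the proportional cover of the four
NLCD developed classes, and area-weighted population and housing density —
enter a correlation-matrix PCA; components with eigenvalue > 1 are
retained and oriented so higher scores mean more urban. Landscape
heterogeneity covariates (species-matched forest amount, patch density,
clumpiness, agriculture, elevation mean/range, Shannon diversity) and
habitat/detectability covariates accompany the index.

**Stage 1 — per-species, per-radius model averaging.** Predictors are
divided by their partial standard deviations,
`s*_j = s_j · √(1/VIF_j) · √((n−1)/(n−p))`, then standardized. All 2^p
predictor subsets are fit as logistic occurrence models; with Akaike
weights `w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)` over the ΔAIC ≤ 2 set, the
urbanization coefficient is *full* model-averaged (`β̄ = Σ w_i β_i`, zero
when absent) with unconditional standard error
`SE = Σ w_i √(var_i + (β_i − β̄)²)`. The species' **scale of effect** is
the radius maximizing `|β̄|` (unimodal candidate sets only).

**Stage 2 — trait meta-regression.** Stage-1 effect sizes (weighted by
1/SE²) and scales of effect are regressed on species traits via
all-subsets Gaussian models with the same AIC averaging (K counts
coefficients + intercept + error SD), in two groups: traits passing a
univariate adjusted-R² > 0 screen (complete-case species) and traits
observed for every species. A univariate PGLS screen estimates Pagel's λ
by maximum likelihood per trait to check that phylogenetic signal does not
violate model assumptions.

A forest-dependency classifier (cumulative species counts vs cumulative
forest amount, max-gap statistic with a permutation null) selects the
species entering stage 1.

## Worked example

```python
from urbanscale.report import run_pipeline

results = run_pipeline(
    {"seed": 7, "extent_m": 9000.0, "radii_km": [0.5, 1], "n_locations": 100,
     "n_species": 10, "n_permutations": 200, "noise_sd": 0.3},
    out_dir="demo_run",
)
print(results["stage1"].responses.head(4).to_string(index=False))
```

prints

```
species_id   n    effect       se  scale_km
      S000 100 -0.849693 0.391331       0.5
      S001 100  0.095159 0.198484       1.0
      S002 100 -0.505888 0.398797       1.0
      S003 100 -2.251060 1.428896       1.0
```

Each row is one simulated species: `effect` is the model-averaged
urbanization coefficient (log-odds of occurrence per SD of the
urbanization score) at the species' selected scale of effect, with its
unconditional SE; negative values mean the species becomes less likely to
occur as landscapes urbanize. `results["summary"]` holds the
cross-species statistics (here 9 species survive averaging: mean effect
−0.48, 4 positive / 5 negative, mean scale 0.89 km), and `demo_run/`
contains every artifact (rasters, metrics, candidate-model tables,
trait-effect tables, manifest). The same stages are available as CLI
subcommands: `urbanscale simulate | metrics | dependency | stage1 |
stage2 | report | pipeline`.

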