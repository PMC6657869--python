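"""Parameter-recovery experiments: the package's own calibration studies.

Each experiment simulates data with known ground truth at the study's
conditions and measures how well the corresponding stage recovers it:

* :func:`stage1_recovery` -- one landscape, 2000 count locations, 50
  species with a strong urbanization coefficient (-1 log-odds per SD)
  acting at a known radius; reports the fraction of species whose selected
  scale of effect is exactly the true radius and the fraction whose
  averaged coefficient falls within 2 unconditional SEs of the truth.
* :func:`stage2_recovery` -- replicated 60-species trait tables with a
  single true trait effect (+0.5 per SD on granivory) or none; reports the
  detection rate of the true effect and, under the null, per-trait 95%
  interval coverage of zero.
* :func:`lambda_recovery` -- Pagel's-lambda estimation on 64-tip Yule
  trees under full Brownian motion and under independence.

These functions power both the acceptance tests and the standalone
acceptance script.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from urbanscale.landscape import LandscapeConfig, generate_landscape
from urbanscale.metrics import assemble_metrics
from urbanscale.phylo import TraitSpec, generate_traits_and_tree, simulate_bm, tree_vcv, yule_tree
from urbanscale.stage1 import run_stage1
from urbanscale.stage2 import pgls_lambda, trait_model_average
from urbanscale.survey import TruthRecord, place_count_locations, simulate_occurrences

log = logging.getLogger(__name__)

STAGE1_PREDICTORS = ["urb1", "forest", "agriculture", "elev_mean", "shannon"]


def stage1_recovery(
    seed: int,
    n_locations: int = 2000,
    n_species: int = 50,
    beta_true: float = -1.0,
    scales_km: tuple[float, ...] = (0.5, 1.0, 2.0),
    extent_m: float = 32_000.0,
    cell_size: float = 80.0,
) -> dict:
    """Scale-of-effect and effect-size recovery at the study's conditions.

    Each species is an independent replicate: occurrences are Bernoulli
    draws with coefficient ``beta_true`` on the standardized urbanization
    score at its true radius (cycling through ``scales_km``), plus modest
    nuisance effects on elevation (-0.3 per SD) and the local land-use
    change flag (+0.2). Nuisance effects sit on covariates that are not
    scale-entangled proxies of urbanization, because the recovery target is
    the urbanization term's own radius. Coefficient calibration is assessed
    at the true radius.
    """
    cfg = LandscapeConfig(
        extent_m=extent_m,
        cell_size=cell_size,
        seed=seed,
        max_radius_m=max(scales_km) * 1000.0,
    )
    stack = generate_landscape(cfg)
    design = place_count_locations(
        stack, n_locations, seed=seed + 1, edge_margin_m=max(scales_km) * 1000.0
    )
    metrics, _ = assemble_metrics(
        stack, design, radii_km=scales_km, include_patch_metrics=False
    )
    truths = [
        TruthRecord(
            species_id=f"R{i:03d}",
            beta_true=beta_true,
            scale_true_km=scales_km[i % len(scales_km)],
            alpha=0.0,
            gammas={"elev_mean": -0.3, "landuse_change": 0.2},
        )
        for i in range(n_species)
    ]
    detections = simulate_occurrences(design, metrics, truths, seed=seed + 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_stage1(metrics, detections, predictors=STAGE1_PREDICTORS, radii_km=scales_km)

    truth_by_id = {t.species_id: t for t in truths}
    resp = result.responses.set_index("species_id")
    per_radius = result.per_radius.set_index(["species_id", "radius_km"])
    correct_scale, covered = [], []
    for sid, t in truth_by_id.items():
        if sid not in resp.index:
            continue
        correct_scale.append(resp.loc[sid, "scale_km"] == t.scale_true_km)
        row = per_radius.loc[(sid, t.scale_true_km)]
        covered.append(abs(row["effect"] - t.beta_true) <= 2.0 * row["se"])
    return {
        "n_species": len(correct_scale),
        "n_locations": len(design),
        "scale_accuracy": float(np.mean(correct_scale)),
        "beta_within_2se": float(np.mean(covered)),
        "responses": result.responses,
    }


STAGE2_TRAITS = [
    TraitSpec("granivory", "binary", prevalence=0.3),
    TraitSpec("frugivory", "binary", prevalence=0.3),
    TraitSpec("cavity_nesting", "binary", prevalence=0.25),
    TraitSpec("resident", "binary", prevalence=0.4),
    TraitSpec("clutch_size", "continuous", loc=4.0, scale=1.0),
    TraitSpec("fledglings_per_clutch", "continuous", loc=3.0, scale=1.0),
]


def stage2_recovery(
    seed: int,
    n_replicates: int = 50,
    n_species: int = 60,
    effect: float = 0.5,
    effect_trait: str = "granivory",
    noise_sd: float = 0.1,
    response_se: float = 0.1,
) -> dict:
    """Trait-effect detection and null calibration for stage 2.

    Signal replicates put a ``+effect`` per-SD weight on one trait; the
    detection criterion is that the trait appears in the delta <= 2
    best-model set with a positive averaged coefficient. Null replicates
    have no trait effects; coverage is the per-trait fraction of replicates
    whose 95% interval (coef +/- 1.96 * unconditional SE) covers zero.
    """
    detected = []
    coverage = {s.name: [] for s in STAGE2_TRAITS}
    for rep in range(n_replicates):
        for null in (False, True):
            traits, _, truths = generate_traits_and_tree(
                n_species,
                seed=seed + 1000 * rep + (500 if null else 0),
                trait_specs=STAGE2_TRAITS,
                lambda_true=0.0,
                weights_beta={} if null else {effect_trait: effect},
                noise_sd=noise_sd,
            )
            y = pd.Series(
                [t.beta_true for t in truths], index=traits.index, name="effect"
            )
            w = pd.Series(1.0 / response_se**2, index=traits.index)
            ms = trait_model_average(y, traits, weights=w, response_name="effect")
            if null:
                for e in ms.effects:
                    coverage[e.trait].append(abs(e.coef) <= 1.96 * e.se if e.se > 0 else True)
            else:
                e = next(e for e in ms.effects if e.trait == effect_trait)
                detected.append(e.in_best_models and e.coef > 0)
    return {
        "n_replicates": n_replicates,
        "detection_rate": float(np.mean(detected)),
        "null_coverage": {k: float(np.mean(v)) for k, v in coverage.items()},
        "min_null_coverage": float(min(np.mean(v) for v in coverage.values())),
    }


def lambda_recovery(
    seed: int, n_replicates: int = 25, n_tips: int = 64
) -> dict:
    """Pagel's-lambda recovery: responses simulated under lambda = 1
    Brownian motion (signal) and i.i.d. noise (null) on Yule trees, with an
    independent predictor."""
    rng = np.random.default_rng(seed)
    lam_bm, lam_null, p_null = [], [], []
    for _ in range(n_replicates):
        tree = yule_tree(n_tips, rng)
        labels, c = tree_vcv(tree)
        x = pd.Series(rng.standard_normal(n_tips), index=labels)
        y_bm = pd.Series(simulate_bm(c, 1.0, rng)[0], index=labels)
        y_iid = pd.Series(rng.standard_normal(n_tips), index=labels)
        lam_bm.append(pgls_lambda(x, y_bm, tree).lambda_hat)
        r0 = pgls_lambda(x, y_iid, tree)
        lam_null.append(r0.lambda_hat)
        p_null.append(r0.p_value)
    return {
        "n_replicates": n_replicates,
        "mean_lambda_bm": float(np.mean(lam_bm)),
        "mean_lambda_null": float(np.mean(lam_null)),
        "null_nonsignificant_rate": float(np.mean(np.asarray(p_null) >= 0.05)),
    }
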