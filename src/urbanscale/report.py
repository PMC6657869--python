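"""Cross-species summaries, packaged reference tables and the end-to-end
pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from urbanscale import io
from urbanscale.dependency import run_dependency
from urbanscale.landscape import LandscapeConfig, generate_landscape
from urbanscale.metrics import assemble_metrics
from urbanscale.phylo import default_trait_specs, generate_traits_and_tree
from urbanscale.stage1 import run_stage1
from urbanscale.stage2 import run_stage2
from urbanscale.survey import place_count_locations, simulate_occurrences

log = logging.getLogger(__name__)


@dataclass
class SummaryStats:
    """Cross-species summary of stage-1 outputs (sample SD, n-1)."""

    n_species: int
    mean_effect: float
    sd_effect: float
    min_effect: float
    max_effect: float
    n_positive: int
    n_negative: int
    n_zero: int
    mean_scale_km: float
    sd_scale_km: float


def summarize_effects(
    responses: pd.DataFrame, effect_col: str = "effect", scale_col: str = "scale_km"
) -> SummaryStats:
    """Arithmetic means, sample SDs, strict sign counts and the effect-size
    range over a per-species response table. SDs are reported as NaN for a
    single species. Zero effects count as neither positive nor negative."""
    if len(responses) == 0:
        raise ValueError("empty response table")
    eff = responses[effect_col].to_numpy(dtype=float)
    sca = responses[scale_col].to_numpy(dtype=float)
    one = len(eff) == 1
    return SummaryStats(
        n_species=len(eff),
        mean_effect=float(eff.mean()),
        sd_effect=float("nan") if one else float(eff.std(ddof=1)),
        min_effect=float(eff.min()),
        max_effect=float(eff.max()),
        n_positive=int((eff > 0).sum()),
        n_negative=int((eff < 0).sum()),
        n_zero=int((eff == 0).sum()),
        mean_scale_km=float(sca.mean()),
        sd_scale_km=float("nan") if one else float(sca.std(ddof=1)),
    )


def _packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("urbanscale.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_table1() -> pd.DataFrame:
    """The published per-species summary table (transcribed fixture):
    one row per species with n, effect, se, scale_km."""
    df = _packaged_csv("pbba_table1.csv")
    return df.rename(columns={"common_name": "species_id"})


def load_model_selection_tables() -> pd.DataFrame:
    """The published stage-2 best-model tables (transcribed fixture)."""
    return _packaged_csv("model_selection_tables.csv")


def run_pipeline(config, out_dir=None) -> dict:
    """simulate -> metrics -> dependency filter -> stage 1 -> stage 2 ->
    report, writing all artifacts plus a manifest under ``out_dir``.

    ``config`` is a YAML path or dict (see :data:`urbanscale.io.DEFAULT_CONFIG`).
    Identical config and seed give identical outputs. Returns a dict of the
    in-memory results keyed by stage.
    """
    cfg = io.load_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    radii = [float(r) for r in cfg["radii_km"]]

    lcfg = LandscapeConfig(
        extent_m=float(cfg["extent_m"]),
        cell_size=float(cfg["cell_size"]),
        urban_gradient=float(cfg["urban_gradient"]),
        forest_target=float(cfg["forest_target"]),
        seed=seed,
        max_radius_m=max(radii) * 1000.0,
    )
    stack = generate_landscape(lcfg)
    io.save_stack(stack, out / "landscape")

    design = place_count_locations(
        stack, cfg["n_locations"], seed=seed + 1, edge_margin_m=max(radii) * 1000.0
    )
    io.save_design(design, out / "design.csv")

    metrics, pca = assemble_metrics(stack, design, radii_km=radii)
    metrics.to_csv(out / "metrics.csv", index=False)
    (out / "pca.json").write_text(
        json.dumps({str(r): json.loads(p.to_json()) for r, p in pca.items()}, indent=1)
    )

    traits, tree, truths = generate_traits_and_tree(
        cfg["n_species"],
        seed=seed + 2,
        trait_specs=default_trait_specs(missing_rate=float(cfg["missing_rate"])),
        lambda_true=float(cfg["lambda_true"]),
        weights_beta=cfg["trait_weights_beta"],
        weights_scale=cfg["trait_weights_scale"],
        noise_sd=float(cfg["noise_sd"]),
        beta_mean=float(cfg["beta_mean"]),
        radii_km=radii,
    )
    traits.to_csv(out / "traits.csv")
    io.save_tree(tree, out / "tree.nwk")
    io.save_truths(truths, out / "truth.json")

    detections = simulate_occurrences(design, metrics, truths, seed=seed + 3)
    io.save_detections(detections, out / "detections.csv")

    dependency = run_dependency(
        detections,
        metrics,
        radii_km=radii,
        alpha=float(cfg["alpha"]),
        n_permutations=int(cfg["n_permutations"]),
        seed=seed + 4,
    )
    dependency.to_csv(out / "dependency.csv", index=False)
    kept = set(dependency[dependency.keep]["species_id"])
    det_kept = detections.table[detections.table.species_id.isin(kept)]

    stage1 = run_stage1(
        metrics,
        det_kept,
        predictors=list(cfg["predictors"]),
        radii_km=radii,
        cap=int(cfg["subset_cap"]),
    )
    stage1.responses.to_csv(out / "species_responses.csv", index=False)
    stage1.per_radius.to_csv(out / "per_radius.csv", index=False)

    results: dict = {
        "stack": stack,
        "design": design,
        "metrics": metrics,
        "dependency": dependency,
        "stage1": stage1,
        "truths": truths,
    }
    if len(stage1.responses) >= 8:
        stage2 = run_stage2(
            stage1.responses,
            traits,
            tree=tree,
            alpha=float(cfg["alpha"]),
        )
        for resp, table in stage2.effects.items():
            table.to_csv(out / f"trait_effects_{resp}.csv", index=False)
        for (resp, grp), table in stage2.selection_tables.items():
            table.to_csv(out / f"model_selection_{resp}_{grp}.csv", index=False)
        if stage2.pgls is not None:
            stage2.pgls.to_csv(out / "pgls_screen.csv", index=False)
        results["stage2"] = stage2
    else:
        log.warning("too few species responses (%d) for stage 2", len(stage1.responses))

    summary = summarize_effects(stage1.responses)
    (out / "summary.json").write_text(json.dumps(asdict(summary), indent=1))
    results["summary"] = summary

    from urbanscale import __version__

    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_sha256": cfg_hash,
        "seeds": {
            "landscape": seed,
            "design": seed + 1,
            "traits": seed + 2,
            "occurrences": seed + 3,
            "dependency": seed + 4,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return results
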