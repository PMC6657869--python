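"""File IO: rasters (single-band TIFF with grid metadata), CSV tables,
Newick trees, JSON truth records and YAML run configs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import tifffile
import yaml

from urbanscale.landscape import LandscapeStack
from urbanscale.survey import DetectionTable, SurveyDesign, TruthRecord


def write_raster(path, array: np.ndarray, cell_size: float, origin=(0.0, 0.0)) -> None:
    """Single-band TIFF; cell size (m) and origin stored in the description."""
    meta = {"cell_size_m": cell_size, "origin": list(origin)}
    tifffile.imwrite(str(path), array, description=json.dumps(meta))


def read_raster(path) -> tuple[np.ndarray, float, tuple[float, float]]:
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        meta = json.loads(page.tags["ImageDescription"].value)
    return arr, float(meta["cell_size_m"]), tuple(meta["origin"])


_SURFACES = ("landcover", "pop_density", "housing_density", "elevation")


def save_stack(stack: LandscapeStack, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _SURFACES:
        write_raster(directory / f"{name}.tif", getattr(stack, name), stack.cell_size, stack.origin)


def load_stack(directory) -> LandscapeStack:
    directory = Path(directory)
    grids = {}
    cell_size, origin = None, None
    for name in _SURFACES:
        arr, cell_size, origin = read_raster(directory / f"{name}.tif")
        grids[name] = arr
    return LandscapeStack(cell_size=cell_size, origin=origin, **grids)


def save_design(design: SurveyDesign, path) -> None:
    design.locations.to_csv(path, index=False)


def load_design(path) -> SurveyDesign:
    return SurveyDesign(locations=pd.read_csv(path))


def save_detections(detections: DetectionTable, path) -> None:
    detections.table.to_csv(path, index=False)


def load_detections(path) -> DetectionTable:
    return DetectionTable(table=pd.read_csv(path))


def save_truths(truths: list[TruthRecord], path) -> None:
    Path(path).write_text(json.dumps([asdict(t) for t in truths], indent=1))


def load_truths(path) -> list[TruthRecord]:
    return [TruthRecord(**d) for d in json.loads(Path(path).read_text())]


def save_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")


def load_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


CONFIG_KEYS = {
    "seed": int,
    "extent_m": (int, float),
    "cell_size": (int, float),
    "urban_gradient": (int, float),
    "forest_target": (int, float),
    "radii_km": list,
    "n_locations": int,
    "n_species": int,
    "lambda_true": (int, float),
    "beta_mean": (int, float),
    "noise_sd": (int, float),
    "trait_weights_beta": dict,
    "trait_weights_scale": dict,
    "missing_rate": (int, float),
    "predictors": list,
    "alpha": (int, float),
    "n_permutations": int,
    "subset_cap": int,
    "out_dir": str,
}

DEFAULT_CONFIG = {
    "seed": 0,
    "extent_m": 16_000.0,
    "cell_size": 60.0,
    "urban_gradient": 1.0,
    "forest_target": 0.58,
    "radii_km": [0.2, 0.5, 1, 2],
    "n_locations": 200,
    "n_species": 12,
    "lambda_true": 0.0,
    "beta_mean": -0.36,
    "noise_sd": 0.3,
    "trait_weights_beta": {"granivory": 0.4, "clutch_size": 0.2},
    "trait_weights_scale": {"granivory": 0.5, "wingspan_cm": 0.3},
    "missing_rate": 0.1,
    "predictors": ["urb1", "forest", "agriculture", "elev_mean", "shannon"],
    "alpha": 0.05,
    "n_permutations": 200,
    "subset_cap": 15,
    "out_dir": "urbanscale_run",
}


def load_config(path_or_dict) -> dict:
    """Load and validate a run config; unknown or mistyped keys error."""
    if isinstance(path_or_dict, (str, Path)):
        cfg = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        cfg = dict(path_or_dict)
    bad = []
    for key, val in cfg.items():
        if key not in CONFIG_KEYS:
            bad.append(f"unknown key {key!r}")
        elif not isinstance(val, CONFIG_KEYS[key]):
            bad.append(f"key {key!r} has type {type(val).__name__}")
    if bad:
        raise ValueError("invalid config: " + "; ".join(bad))
    merged = dict(DEFAULT_CONFIG)
    merged.update(cfg)
    return merged
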