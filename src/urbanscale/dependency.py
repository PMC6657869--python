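"""Forest-dependency classification from cumulative count/forest curves.

Locations are ordered by ascending forest amount; a species' cumulative
count fraction along that ordering is compared with the cumulative forest
fraction. The maximum gap D between the two curves is a Kolmogorov-Smirnov
style statistic, but because counts act as weights rather than i.i.d.
draws, significance comes from a seeded permutation null (counts shuffled
over locations) instead of the asymptotic KS distribution.

A species votes *forest-dependent* at a radius when the curves are
indistinguishable (individuals accumulate at the rate forest does) or when
they differ with counts concentrated in the most-forested landscapes; it
votes *forest-independent* when counts concentrate in the least-forested
landscapes. The final label is the majority vote across radii, ties going
to forest-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FOREST_DEPENDENT = "forest-dependent"
FOREST_INDEPENDENT = "forest-independent"
MIN_OCCUPIED_LOCATIONS = 30

EXCLUSION_FLAGS = ("hybrid", "irregular_breeder", "raptor", "waterfowl", "nocturnal")


def eligibility_filter(
    detections,
    species_flags: pd.DataFrame | None = None,
    min_locations: int = MIN_OCCUPIED_LOCATIONS,
) -> pd.DataFrame:
    """Keep/drop decision per species with the reason.

    Species occupying fewer than ``min_locations`` locations are dropped;
    ``species_flags`` (indexed by species_id, boolean columns named after
    ``EXCLUSION_FLAGS``) applies the categorical exclusions. A missing flag
    table means only the count filter applies.
    """
    det = detections.table if hasattr(detections, "table") else detections
    occupied = (
        det[det.detected == 1].groupby("species_id")["location_id"].nunique()
    )
    rows = []
    for species_id in det["species_id"].unique():
        n_occ = int(occupied.get(species_id, 0))
        keep, reason = True, ""
        if species_flags is not None and species_id in species_flags.index:
            for flag in EXCLUSION_FLAGS:
                if flag in species_flags.columns and bool(species_flags.loc[species_id, flag]):
                    keep, reason = False, flag
                    break
        if keep and n_occ < min_locations:
            keep, reason = False, "min occurrence"
        rows.append(
            {"species_id": species_id, "keep": keep, "reason": reason, "n_occupied": n_occ}
        )
    return pd.DataFrame(rows)


def cumulative_curves(counts, forest) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(count CDF, forest CDF, tie-boundary mask) over locations ordered by
    ascending forest amount.

    The mask marks the last index of each group of equal forest values;
    evaluating the gap only there makes D invariant to relabeling tied
    locations.
    """
    counts = np.asarray(counts, dtype=float)
    forest = np.asarray(forest, dtype=float)
    if counts.shape != forest.shape:
        raise ValueError("counts and forest amounts must align")
    total = counts.sum()
    if total == 0:
        raise ValueError("species has zero total count")
    order = np.argsort(forest, kind="stable")
    f = forest[order]
    count_cdf = np.cumsum(counts[order]) / total
    forest_cdf = np.cumsum(f) / f.sum()
    boundary = np.ones(len(f), dtype=bool)
    boundary[:-1] = f[:-1] != f[1:]
    return count_cdf, forest_cdf, boundary


def ks_statistic(counts, forest) -> tuple[float, str]:
    """Max |gap| between the two CDFs at tie boundaries, and the deviation
    direction: ``high_forest`` when counts lag the forest curve (individuals
    concentrated in the most-forested landscapes), else ``low_forest``."""
    count_cdf, forest_cdf, boundary = cumulative_curves(counts, forest)
    gaps = (count_cdf - forest_cdf)[boundary]
    i = int(np.argmax(np.abs(gaps)))
    direction = "high_forest" if gaps[i] < 0 else "low_forest"
    return float(np.abs(gaps[i])), direction


@dataclass
class DependencyResult:
    species_id: str
    d_by_radius: dict[float, float] = field(default_factory=dict)
    p_by_radius: dict[float, float] = field(default_factory=dict)
    direction_by_radius: dict[float, str] = field(default_factory=dict)
    votes: dict[float, str] = field(default_factory=dict)
    classification: str = FOREST_DEPENDENT


def classify_species(
    species_id: str,
    counts_by_radius: dict[float, np.ndarray],
    forest_by_radius: dict[float, np.ndarray],
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> DependencyResult:
    """Per-radius permutation test of the max-gap statistic, then majority
    vote across radii (tie -> forest-dependent)."""
    rng = np.random.default_rng(seed)
    res = DependencyResult(species_id=species_id)
    for radius in sorted(counts_by_radius):
        counts = np.asarray(counts_by_radius[radius], dtype=float)
        forest = np.asarray(forest_by_radius[radius], dtype=float)
        d_obs, direction = ks_statistic(counts, forest)
        exceed = 0
        for _ in range(n_permutations):
            d_perm, _ = ks_statistic(rng.permutation(counts), forest)
            if d_perm >= d_obs:
                exceed += 1
        p = (exceed + 1) / (n_permutations + 1)
        res.d_by_radius[radius] = d_obs
        res.p_by_radius[radius] = p
        res.direction_by_radius[radius] = direction
        if p >= alpha or direction == "high_forest":
            res.votes[radius] = FOREST_DEPENDENT
        else:
            res.votes[radius] = FOREST_INDEPENDENT
    n_dep = sum(v == FOREST_DEPENDENT for v in res.votes.values())
    res.classification = (
        FOREST_DEPENDENT if n_dep >= len(res.votes) / 2 else FOREST_INDEPENDENT
    )
    return res


def run_dependency(
    detections,
    metrics: pd.DataFrame,
    forest_col: str = "forest_total",
    radii_km=None,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    species_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Eligibility filter + classification for every species in a detection
    table; returns one row per species with per-radius D values and the
    final label (NaN columns for dropped species)."""
    det = detections.table if hasattr(detections, "table") else detections
    elig = eligibility_filter(detections, species_flags=species_flags).set_index("species_id")
    radii = sorted(radii_km) if radii_km is not None else sorted(metrics["radius_km"].unique())
    rows = []
    for species_id, sdet in det.groupby("species_id"):
        row: dict = {
            "species_id": species_id,
            "keep": bool(elig.loc[species_id, "keep"]),
            "drop_reason": elig.loc[species_id, "reason"],
            "classification": None,
        }
        if row["keep"]:
            counts_by_r, forest_by_r = {}, {}
            s = sdet.set_index("location_id")["count"]
            for radius in radii:
                m = metrics[metrics.radius_km == radius].set_index("location_id")
                common = m.index.intersection(s.index)
                counts_by_r[radius] = s.loc[common].to_numpy()
                forest_by_r[radius] = m.loc[common, forest_col].to_numpy()
            res = classify_species(
                species_id,
                counts_by_r,
                forest_by_r,
                alpha=alpha,
                n_permutations=n_permutations,
                seed=seed,
            )
            row["classification"] = res.classification
            for radius in radii:
                row[f"D_{radius}"] = res.d_by_radius[radius]
                row[f"vote_{radius}"] = res.votes[radius]
        rows.append(row)
    return pd.DataFrame(rows)
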