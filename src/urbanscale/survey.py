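"""Survey design and occurrence simulation.

Count locations are placed like roadside point counts in a forested state:
candidate cells must have >50% forest within 0.2 km, and accepted points
must be pairwise at least 400 m apart. Occurrences are independent
Bernoulli draws from a logistic model whose urbanization coefficient acts
at one known radius per species -- the ground truth that stage-1 recovery
tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve
from scipy.special import expit

from urbanscale import nlcd
from urbanscale.landscape import LandscapeStack

MIN_SPACING_M = 400.0
FOREST_RULE_RADIUS_M = 200.0
FOREST_RULE_MIN = 0.5

DESIGN_COLUMNS = [
    "location_id",
    "x",
    "y",
    "observer",
    "start_time",
    "julian_date",
    "year",
    "landuse_change",
    "dominant_habitat",
]


@dataclass
class SurveyDesign:
    """Point-count locations with detectability and habitat covariates.

    ``locations`` has one row per point with columns
    ``location_id, x, y`` (planar meters),
    detectability covariates ``observer`` (categorical id), ``start_time``
    (minutes after midnight), ``julian_date``, ``year``, and habitat
    covariates ``landuse_change`` (0/1) and ``dominant_habitat``
    (categorical).
    """

    locations: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(DESIGN_COLUMNS) - set(self.locations.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.locations)

    def validate(self, stack: LandscapeStack) -> None:
        """Re-check the spacing and forest-rule constraints against a stack."""
        xy = self.locations[["x", "y"]].to_numpy()
        if len(xy) > 1:
            from scipy.spatial.distance import pdist

            if pdist(xy).min() < MIN_SPACING_M - 1e-9:
                raise ValueError("locations closer than the 400 m minimum spacing")
        from urbanscale.metrics import extract_buffer, proportional_cover

        for _, row in self.locations.iterrows():
            buf = extract_buffer(stack, (row.x, row.y), FOREST_RULE_RADIUS_M)
            if proportional_cover(buf, stack, nlcd.FOREST) <= FOREST_RULE_MIN:
                raise ValueError(f"location {row.location_id} fails the >50% forest rule")


@dataclass
class TruthRecord:
    """Ground truth for one simulated species."""

    species_id: str
    beta_true: float  # log-odds per SD of urbanization score, at scale_true_km
    scale_true_km: float
    alpha: float = 0.0
    gammas: dict[str, float] = field(default_factory=dict)
    trait_weights_beta: dict[str, float] = field(default_factory=dict)
    trait_weights_scale: dict[str, float] = field(default_factory=dict)


@dataclass
class DetectionTable:
    """Per (species, location) detections; ``detected == (count >= 1)``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = {"species_id", "location_id", "detected", "count"} - set(t.columns)
        if missing:
            raise ValueError(f"detection table missing columns: {sorted(missing)}")
        if ((t["count"] >= 1) != (t["detected"] == 1)).any():
            raise ValueError("invariant violated: detected must equal (count >= 1)")

    def occupied_locations(self) -> pd.Series:
        """Number of locations at which each species was detected."""
        d = self.table[self.table.detected == 1]
        return d.groupby("species_id")["location_id"].nunique()


def forest_fraction_map(stack: LandscapeStack, radius_m: float = FOREST_RULE_RADIUS_M) -> np.ndarray:
    """Per-cell forest proportion within ``radius_m`` (cell-center rule)."""
    r_cells = radius_m / stack.cell_size
    k = int(np.floor(r_cells))
    oy, ox = np.mgrid[-k : k + 1, -k : k + 1]
    kernel = ((oy**2 + ox**2) < r_cells**2).astype(float)
    forest = np.isin(stack.landcover, list(nlcd.FOREST)).astype(float)
    num = convolve(forest, kernel, mode="constant", cval=0.0)
    den = convolve(np.ones_like(forest), kernel, mode="constant", cval=0.0)
    return num / den


def place_count_locations(
    stack: LandscapeStack,
    n: int,
    seed: int,
    min_spacing_m: float = MIN_SPACING_M,
    edge_margin_m: float = 0.0,
    n_observers: int = 12,
) -> SurveyDesign:
    """Place ``n`` admissible count locations on ``stack``.

    Cells passing the >50%-forest-within-0.2-km rule (and at least
    ``edge_margin_m`` from the grid border, so downstream buffers stay
    complete) are visited in seeded random order; a candidate is accepted
    when it is at least ``min_spacing_m`` from every already-accepted point.

    Raises ``RuntimeError`` naming the binding constraint when fewer than
    ``n`` admissible sites exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    frac = forest_fraction_map(stack)
    admissible = frac > FOREST_RULE_MIN
    if edge_margin_m > 0:
        m = int(np.ceil(edge_margin_m / stack.cell_size))
        border = np.zeros(stack.shape, dtype=bool)
        border[m:-m, m:-m] = True
        admissible &= border
    cand = np.flatnonzero(admissible)
    if cand.size == 0:
        raise RuntimeError(
            "no admissible location: no cell satisfies the >50% forest rule"
            + (" within the border margin" if edge_margin_m > 0 else "")
        )
    order = rng.permutation(cand)

    # greedy min-distance acceptance with a coarse spatial hash
    cell = stack.cell_size
    bin_size = min_spacing_m
    accepted: list[tuple[int, int]] = []
    bins: dict[tuple[int, int], list[tuple[float, float]]] = {}
    ncol = stack.shape[1]
    for flat in order:
        row, col = divmod(int(flat), ncol)
        x, y = stack.cell_center(row, col)
        bx, by = int(x // bin_size), int(y // bin_size)
        ok = True
        for nb in (
            (bx + dx, by + dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
        ):
            for px, py in bins.get(nb, ()):
                if (px - x) ** 2 + (py - y) ** 2 < min_spacing_m**2:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            accepted.append((row, col))
            bins.setdefault((bx, by), []).append((x, y))
            if len(accepted) == n:
                break
    if len(accepted) < n:
        raise RuntimeError(
            f"only {len(accepted)} of {n} locations placeable: the 400 m "
            "minimum-spacing constraint binds before the forest rule does"
        )

    rows = np.array([rc[0] for rc in accepted])
    cols = np.array([rc[1] for rc in accepted])
    xs = stack.origin[0] + (cols + 0.5) * cell
    ys = stack.origin[1] + (rows + 0.5) * cell
    habitat = [
        nlcd.HABITAT_LABELS.get(int(stack.landcover[r, c]), "other")
        for r, c in accepted
    ]
    table = pd.DataFrame(
        {
            "location_id": [f"L{i:05d}" for i in range(n)],
            "x": xs,
            "y": ys,
            "observer": rng.integers(0, n_observers, size=n),
            "start_time": rng.integers(300, 600, size=n),
            "julian_date": rng.integers(145, 186, size=n),
            "year": rng.integers(2004, 2010, size=n),
            "landuse_change": rng.binomial(1, 0.1, size=n),
            "dominant_habitat": habitat,
        }
    )
    return SurveyDesign(locations=table)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v, dtype=float)
    return (v - v.mean()) / sd


def simulate_occurrences(
    design: SurveyDesign,
    metrics: pd.DataFrame,
    truths: list[TruthRecord],
    seed: int,
    urb_col: str = "urb1",
) -> DetectionTable:
    """Draw Bernoulli detections from the logistic ground-truth model.

    Detection probability at location i for species s is
    ``expit(alpha + beta_true * U_i(s_true) + sum_j gamma_j * z_ij)`` where
    ``U`` is the urbanization score at the species' true radius,
    standardized across locations (so ``beta_true`` is log-odds per SD),
    and the ``z`` are standardized nuisance covariates named by
    ``TruthRecord.gammas`` (metric or design columns).
    """
    rng = np.random.default_rng(seed)
    loc_order = design.locations["location_id"].to_numpy()
    by_radius = {
        r: g.set_index("location_id").reindex(loc_order)
        for r, g in metrics.groupby("radius_km")
    }
    frames = []
    for truth in truths:
        if truth.scale_true_km not in by_radius:
            raise ValueError(
                f"no metrics at radius {truth.scale_true_km} km for species "
                f"{truth.species_id}"
            )
        at_scale = by_radius[truth.scale_true_km]
        u = at_scale[urb_col].to_numpy(dtype=float)
        if np.isnan(u).any():
            raise ValueError(
                f"urbanization score missing for some locations at radius "
                f"{truth.scale_true_km} km"
            )
        eta = truth.alpha + truth.beta_true * _zscore(u)
        for name, gamma in truth.gammas.items():
            if name in at_scale.columns:
                z = at_scale[name].to_numpy(dtype=float)
            elif name in design.locations.columns:
                z = design.locations[name].to_numpy(dtype=float)
            else:
                raise ValueError(f"nuisance covariate {name!r} not found")
            eta = eta + gamma * _zscore(z)
        detected = rng.binomial(1, expit(eta))
        frames.append(
            pd.DataFrame(
                {
                    "species_id": truth.species_id,
                    "location_id": loc_order,
                    "detected": detected,
                    "count": detected,
                }
            )
        )
    return DetectionTable(table=pd.concat(frames, ignore_index=True))
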