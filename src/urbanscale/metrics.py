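"""Landscape metrics: buffers, cover fractions, FRAGSTATS-style
configuration metrics, Shannon diversity and the PCA urbanization index.

A buffer contains every cell whose *center* lies strictly within the radius
of the center point; buffers whose disc extends past the grid are flagged
incomplete and dropped by :func:`assemble_metrics` (border-omission rule).
Patch delineation uses 8-neighbor connectivity; clumpiness (CLUMPY) uses
rook (4-neighbor) adjacencies counted only between pairs of cells that are
both inside the buffer.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from urbanscale import nlcd
from urbanscale.landscape import LandscapeStack
from urbanscale.survey import SurveyDesign

log = logging.getLogger(__name__)

#: analysis radii (km) spanning one order of magnitude at high density
DEFAULT_RADII_KM = (0.2, 0.5, 1, 2, 4, 6, 8, 10, 12, 16)

EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class Buffer:
    """Cells of a circular landscape around a count location."""

    center: tuple[float, float]
    radius_m: float
    rows: np.ndarray  # grid row indices of member cells
    cols: np.ndarray
    complete: bool  # False if the disc extends beyond the grid

    @property
    def n_cells(self) -> int:
        return len(self.rows)

    def area_m2(self, cell_size: float) -> float:
        return self.n_cells * cell_size**2


def extract_buffer(stack: LandscapeStack, center: tuple[float, float], radius_m: float) -> Buffer:
    """Member cells by the strict cell-center rule; flags incompleteness."""
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    cx, cy = center
    stack.xy_to_rowcol(cx, cy)  # raises if the center is off-grid
    cell = stack.cell_size
    x0, y0 = stack.origin
    nrow, ncol = stack.shape

    lo_col = max(int(np.floor((cx - radius_m - x0) / cell)), 0)
    hi_col = min(int(np.ceil((cx + radius_m - x0) / cell)), ncol - 1)
    lo_row = max(int(np.floor((cy - radius_m - y0) / cell)), 0)
    hi_row = min(int(np.ceil((cy + radius_m - y0) / cell)), nrow - 1)
    rr, cc = np.mgrid[lo_row : hi_row + 1, lo_col : hi_col + 1]
    xs = x0 + (cc + 0.5) * cell
    ys = y0 + (rr + 0.5) * cell
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 < radius_m**2
    if not inside.any():
        # degenerate disc smaller than the cell grid: the containing cell
        row, col = stack.xy_to_rowcol(cx, cy)
        inside = (rr == row) & (cc == col)
    complete = (
        cx - radius_m >= x0
        and cx + radius_m <= x0 + ncol * cell
        and cy - radius_m >= y0
        and cy + radius_m <= y0 + nrow * cell
    )
    return Buffer(
        center=(cx, cy),
        radius_m=radius_m,
        rows=rr[inside].ravel(),
        cols=cc[inside].ravel(),
        complete=complete,
    )


def proportional_cover(buffer: Buffer, stack: LandscapeStack, classes) -> float:
    """Fraction of member cells whose land cover is in ``classes``."""
    if buffer.n_cells == 0:
        raise ValueError("empty buffer")
    classes = list(classes)
    if not classes:
        raise ValueError("empty class set")
    vals = stack.landcover[buffer.rows, buffer.cols]
    return float(np.isin(vals, classes).mean())


def area_weighted_mean(buffer: Buffer, surface: np.ndarray, ignore_missing: bool = False) -> float:
    """Mean of a co-registered surface over member cells.

    Cells are equal-area, so the area-weighted average is the cell mean.
    """
    vals = surface[buffer.rows, buffer.cols].astype(float)
    if np.isnan(vals).any():
        if not ignore_missing:
            raise ValueError("surface contains NaN inside the buffer")
        vals = vals[~np.isnan(vals)]
    return float(vals.mean())


def surface_range(buffer: Buffer, surface: np.ndarray, ignore_missing: bool = False) -> float:
    """max - min of a surface over member cells (e.g. elevation range)."""
    vals = surface[buffer.rows, buffer.cols].astype(float)
    if np.isnan(vals).any():
        if not ignore_missing:
            raise ValueError("surface contains NaN inside the buffer")
        vals = vals[~np.isnan(vals)]
    return float(vals.max() - vals.min())


def _buffer_window(buffer: Buffer, stack: LandscapeStack):
    """Bounding-window views: (landcover window, in-buffer mask)."""
    r0, r1 = buffer.rows.min(), buffer.rows.max()
    c0, c1 = buffer.cols.min(), buffer.cols.max()
    win = stack.landcover[r0 : r1 + 1, c0 : c1 + 1]
    mask = np.zeros(win.shape, dtype=bool)
    mask[buffer.rows - r0, buffer.cols - c0] = True
    return win, mask


def patch_density(buffer: Buffer, stack: LandscapeStack, classes) -> float:
    """Connected components (8-neighbor) of the class per 100 ha of buffer."""
    if buffer.n_cells == 0:
        raise ValueError("empty buffer")
    win, mask = _buffer_window(buffer, stack)
    class_mask = np.isin(win, list(classes)) & mask
    _, n_patches = ndimage.label(class_mask, structure=EIGHT_CONN)
    area_100ha = buffer.area_m2(stack.cell_size) / 1e6  # 100 ha = 1e6 m^2
    return float(n_patches / area_100ha)


def _min_perimeter(area_cells: int) -> int:
    """Minimum edge count of a maximally compact arrangement of n cells."""
    n = int(np.floor(np.sqrt(area_cells)))
    m = area_cells - n * n
    if m == 0:
        return 4 * n
    if m <= n:
        return 4 * n + 2
    return 4 * n + 4


def clumpiness(buffer: Buffer, stack: LandscapeStack, classes) -> float:
    """FRAGSTATS-style clumpiness (CLUMPY) of a class within the buffer.

    With ``g_ii`` the double-count like adjacencies, ``g_i.`` the
    double-count adjacencies of the class to any in-buffer cell, and
    ``min_e`` the minimum perimeter of a maximally compact patch of the
    class' area, the proportion of like adjacencies is
    ``G = g_ii / (g_i. - min_e)`` and

    ``CLUMPY = (G - P) / P`` when ``G < P`` and ``P < 0.5``, else
    ``(G - P) / (1 - P)``,

    giving -1 for maximal dispersion (checkerboard at P = 0.5) and +1 for
    maximal aggregation. Returns NaN when the class is absent. When the
    denominator is non-positive (tiny classes whose compact perimeter
    exceeds their available adjacencies) G falls back to ``g_ii / g_i.``.
    """
    win, mask = _buffer_window(buffer, stack)
    class_mask = np.isin(win, list(classes)) & mask
    area = int(class_mask.sum())
    if area == 0:
        return float("nan")
    p = area / buffer.n_cells
    if p == 1.0:
        return 1.0

    # double-count rook adjacencies, both cells inside the buffer
    like_h = class_mask[:, :-1] & class_mask[:, 1:]
    like_v = class_mask[:-1, :] & class_mask[1:, :]
    g_ii = 2 * (int(like_h.sum()) + int(like_v.sum()))
    any_h = class_mask[:, :-1] & mask[:, 1:]
    any_h2 = mask[:, :-1] & class_mask[:, 1:]
    any_v = class_mask[:-1, :] & mask[1:, :]
    any_v2 = mask[:-1, :] & class_mask[1:, :]
    g_total = int(any_h.sum()) + int(any_h2.sum()) + int(any_v.sum()) + int(any_v2.sum())

    denom = g_total - _min_perimeter(area)
    if denom > 0:
        g = g_ii / denom
    elif g_total > 0:
        g = g_ii / g_total
    else:
        g = 0.0
    g = min(g, 1.0)
    if g < p and p < 0.5:
        return float((g - p) / p)
    return float((g - p) / (1.0 - p))


def shannon_diversity(buffer: Buffer, stack: LandscapeStack) -> float:
    """Shannon diversity H (nats) of land-cover classes in the buffer."""
    if buffer.n_cells == 0:
        raise ValueError("empty buffer")
    vals = stack.landcover[buffer.rows, buffer.cols]
    _, counts = np.unique(vals, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


@dataclass
class PCAIndex:
    """PCA of the urbanization variables at one radius.

    ``loadings`` columns are unit-norm eigenvectors of the correlation
    matrix (one column per retained component), oriented so each retained
    score correlates non-negatively with housing density; ``scores`` are
    the per-landscape component scores (zero mean; variance equals the
    eigenvalue).
    """

    eigenvalues: np.ndarray  # all, non-increasing
    loadings: np.ndarray  # (n_vars, n_retained)
    n_retained: int
    scores: np.ndarray  # (n_landscapes, n_retained)
    variable_names: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": self.variable_names,
                "eigenvalues": self.eigenvalues.tolist(),
                "n_retained": self.n_retained,
                "loadings": self.loadings.tolist(),
            }
        )


def urbanization_pca(
    X,
    housing_col: str | int = "housing_density",
    variable_names: list[str] | None = None,
) -> PCAIndex:
    """PCA (correlation matrix) of urbanization variables across landscapes.

    Components with eigenvalue > 1 are retained (Kaiser rule); if none
    qualifies the first component is retained with a warning. Each retained
    component is sign-oriented so its score correlates non-negatively with
    the housing-density column, keeping "higher score = more urban" stable.
    """
    if isinstance(X, pd.DataFrame):
        variable_names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if variable_names is None:
            variable_names = [f"v{i}" for i in range(arr.shape[1])]
    n, k = arr.shape
    if n < 7:
        raise ValueError("need at least 7 landscapes for a stable PCA")
    sds = arr.std(axis=0, ddof=1)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(f"variable {variable_names[j]!r} is constant")
    z = (arr - arr.mean(axis=0)) / sds
    corr = (z.T @ z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    retained = int(np.sum(eigval > 1.0 + 1e-9))  # tolerance guards exact-unit spectra
    if retained == 0:
        warnings.warn(
            "no eigenvalue > 1; retaining the first component only",
            stacklevel=2,
        )
        retained = 1

    if isinstance(housing_col, str):
        h_idx = variable_names.index(housing_col) if housing_col in variable_names else k - 1
    else:
        h_idx = housing_col
    loadings = eigvec[:, :retained].copy()
    scores = z @ loadings
    for c in range(retained):
        r = float(np.dot(scores[:, c], z[:, h_idx]))
        if r < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return PCAIndex(
        eigenvalues=eigval,
        loadings=loadings,
        n_retained=retained,
        scores=scores,
        variable_names=variable_names,
    )


URBAN_VARIABLES = [
    "dev_open",
    "dev_low",
    "dev_medium",
    "dev_high",
    "pop_density",
    "housing_density",
]


def assemble_metrics(
    stack: LandscapeStack,
    design: SurveyDesign,
    radii_km=DEFAULT_RADII_KM,
    forest_groups: dict[str, frozenset] | None = None,
    include_patch_metrics: bool = True,
) -> tuple[pd.DataFrame, dict[float, PCAIndex]]:
    """One metrics row per (location, radius), plus per-radius PCA indices.

    ``forest_groups`` maps group names to land-cover class sets; a
    ``total`` (all forest classes) group is always computed as the fallback
    for generalist species. Incomplete (border-overlapping) buffers are
    dropped. Location-level habitat and detectability covariates are
    carried through onto every row.

    Returns ``(table, pca_by_radius)``; the table's ``urb1`` (and ``urb2``
    where a second component is retained) are the raw component scores
    (zero mean, variance = eigenvalue).
    """
    groups = dict(forest_groups or {})
    groups.setdefault("total", nlcd.FOREST)

    rows = []
    for radius_km in radii_km:
        radius_m = float(radius_km) * 1000.0
        n_dropped = 0
        for loc in design.locations.itertuples(index=False):
            buf = extract_buffer(stack, (loc.x, loc.y), radius_m)
            if not buf.complete:
                n_dropped += 1
                continue
            rec = {
                "location_id": loc.location_id,
                "radius_km": float(radius_km),
                "dev_open": proportional_cover(buf, stack, {nlcd.DEVELOPED_OPEN}),
                "dev_low": proportional_cover(buf, stack, {nlcd.DEVELOPED_LOW}),
                "dev_medium": proportional_cover(buf, stack, {nlcd.DEVELOPED_MEDIUM}),
                "dev_high": proportional_cover(buf, stack, {nlcd.DEVELOPED_HIGH}),
                "pop_density": area_weighted_mean(buf, stack.pop_density),
                "housing_density": area_weighted_mean(buf, stack.housing_density),
                "agriculture": proportional_cover(buf, stack, nlcd.AGRICULTURE),
                "elev_mean": area_weighted_mean(buf, stack.elevation),
                "elev_range": surface_range(buf, stack.elevation),
                "shannon": shannon_diversity(buf, stack),
            }
            for gname, classes in groups.items():
                rec[f"forest_{gname}"] = proportional_cover(buf, stack, classes)
                if include_patch_metrics:
                    rec[f"pd_{gname}"] = patch_density(buf, stack, classes)
                    rec[f"clumpy_{gname}"] = clumpiness(buf, stack, classes)
            rows.append(rec)
        if n_dropped:
            log.info(
                "radius %.1f km: dropped %d border-overlapping landscapes",
                radius_km,
                n_dropped,
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no complete landscape at any radius")

    pca_by_radius: dict[float, PCAIndex] = {}
    table["urb1"] = np.nan
    table["urb2"] = np.nan
    for radius_km, grp in table.groupby("radius_km"):
        sub = grp[URBAN_VARIABLES]
        # constant variables (e.g. a developed class absent from every
        # forest-constrained buffer at small radii) carry no gradient
        # information; drop them rather than abort the index
        varying = [c for c in sub.columns if sub[c].nunique() > 1]
        if len(varying) < len(sub.columns):
            log.info(
                "radius %.1f km: dropping constant urbanization variables %s",
                radius_km,
                sorted(set(sub.columns) - set(varying)),
            )
        if len(varying) < 2:
            log.warning("radius %.1f km: fewer than 2 varying urbanization variables", radius_km)
            continue
        try:
            pca = urbanization_pca(sub[varying])
        except ValueError as exc:
            log.warning("radius %.1f km: PCA failed (%s); scores left missing", radius_km, exc)
            continue
        pca_by_radius[float(radius_km)] = pca
        table.loc[grp.index, "urb1"] = pca.scores[:, 0]
        if pca.n_retained >= 2:
            table.loc[grp.index, "urb2"] = pca.scores[:, 1]

    covars = design.locations.drop(columns=["x", "y"])
    table = table.merge(covars, on="location_id", how="left")
    return table, pca_by_radius
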