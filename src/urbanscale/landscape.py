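"""Synthetic landscape generation.

Land cover is built from thresholded Gaussian random fields (a standard
neutral-landscape construction): smoothing seeded white noise gives a
spatially autocorrelated surface whose quantiles are cut to hit target
class fractions exactly. An urbanization gradient -- Gaussian kernels
around randomly placed urban centers plus field noise -- orders cells from
rural to urban; the most urban cells become the four developed-intensity
classes, and population and housing density increase monotonically (plus
noise) along the same gradient so the three urbanization measures are
mutually positively correlated, which is what gives the downstream PCA
index a dominant first component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from urbanscale import nlcd


@dataclass
class LandscapeStack:
    """Co-registered land-cover / density / elevation grids.

    All grids share shape; ``cell_size`` is in meters and ``origin`` is the
    planar (x, y) of the lower-left grid corner. Row 0 is the southernmost
    row; cell centers are at ``origin + (index + 0.5) * cell_size``.
    """

    landcover: np.ndarray
    pop_density: np.ndarray
    housing_density: np.ndarray
    elevation: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        shapes = {
            self.landcover.shape,
            self.pop_density.shape,
            self.housing_density.shape,
            self.elevation.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"grids do not share a shape: {shapes}")
        codes = set(np.unique(self.landcover).tolist())
        if not codes <= set(nlcd.LEGEND):
            raise ValueError(f"land-cover codes outside legend: {codes - set(nlcd.LEGEND)}")
        if (self.pop_density < 0).any() or (self.housing_density < 0).any():
            raise ValueError("densities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.landcover.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in meters."""
        return (self.shape[1] * self.cell_size, self.shape[0] * self.cell_size)

    def xy_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = int(np.floor((y - self.origin[1]) / self.cell_size))
        if not (0 <= row < self.shape[0] and 0 <= col < self.shape[1]):
            raise ValueError(f"point ({x}, {y}) lies off the grid")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin[0] + (col + 0.5) * self.cell_size,
            self.origin[1] + (row + 0.5) * self.cell_size,
        )


@dataclass
class LandscapeConfig:
    """Generation parameters.

    ``urban_gradient`` in [0, 1] scales how much of the non-forest remainder
    is developed; 0 yields an all-forest landscape. ``forest_target`` is the
    realized forest fraction for any positive gradient strength (the default
    0.58 matches a predominantly forested temperate state).
    """

    extent_m: float = 20_000.0
    cell_size: float = 60.0
    urban_gradient: float = 1.0
    forest_target: float = 0.58
    seed: int = 0
    n_urban_centers: int = 8
    autocorr_range_m: float = 900.0
    max_radius_m: float | None = None  # validated against extent when given

    def __post_init__(self) -> None:
        if not 0.0 <= self.urban_gradient <= 1.0:
            raise ValueError("urban_gradient must be in [0, 1]")
        if not 0.0 < self.forest_target < 1.0:
            raise ValueError("forest_target must be in (0, 1)")
        if self.max_radius_m is not None and self.extent_m < 2 * self.max_radius_m:
            raise ValueError(
                f"extent {self.extent_m} m is smaller than twice the largest "
                f"analysis radius ({self.max_radius_m} m)"
            )


def _grf(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field via kernel smoothing."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="reflect")
    return (f - f.mean()) / f.std()


def _rank_threshold(score: np.ndarray, eligible: np.ndarray, n_cells: int) -> np.ndarray:
    """Mask of the ``n_cells`` highest-scoring eligible cells."""
    mask = np.zeros(score.shape, dtype=bool)
    if n_cells <= 0:
        return mask
    idx = np.flatnonzero(eligible)
    order = np.argsort(score.ravel()[idx], kind="stable")[::-1]
    mask.ravel()[idx[order[:n_cells]]] = True
    return mask


def generate_landscape(config: LandscapeConfig) -> LandscapeStack:
    """Generate a :class:`LandscapeStack` from a :class:`LandscapeConfig`.

    Deterministic for a given config (all randomness from
    ``default_rng(config.seed)``). Class fractions: for gradient strength
    ``s`` > 0 the forest fraction equals ``forest_target`` (to within one
    cell) and the remainder ``r = 1 - forest_target`` is split as developed
    ``0.55 * s * r``, other (barren) ``0.05 * r``, agriculture the rest.
    ``s = 0`` short-circuits to an all-forest stack.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.extent_m / config.cell_size))
    shape = (n, n)
    ncell = n * n
    sigma = config.autocorr_range_m / config.cell_size

    # urbanization field: urban centers of widely varying size (a few towns
    # down to hamlets) plus fine-scale autocorrelated scatter, so that
    # urbanization intensity genuinely varies across buffer radii and the
    # scale of effect is identifiable
    rows, cols = np.mgrid[0:n, 0:n]
    urban = np.zeros(shape)
    n_centers = max(config.n_urban_centers, 1)
    centers = rng.uniform(0.1 * n, 0.9 * n, size=(n_centers, 2))
    sig_lo, sig_hi = np.log(n / 40.0), np.log(n / 8.0)
    kernel_sigmas = np.exp(rng.uniform(sig_lo, sig_hi, size=n_centers))
    amplitudes = rng.uniform(0.5, 1.5, size=n_centers)
    for (cy, cx), ks, amp in zip(centers, kernel_sigmas, amplitudes):
        d2 = (rows - cy) ** 2 + (cols - cx) ** 2
        urban += amp * np.exp(-d2 / (2 * ks**2))
    urban = (urban - urban.mean()) / urban.std()
    urban = urban + 0.9 * _grf(rng, shape, 0.5 * sigma)

    ag_field = _grf(rng, shape, 2.0 * sigma)
    other_field = _grf(rng, shape, sigma)
    ftype_field = _grf(rng, shape, 1.5 * sigma)
    elev = 350.0 + 80.0 * _grf(rng, shape, 4.0 * sigma) + 6.0 * _grf(rng, shape, sigma)

    landcover = np.empty(shape, dtype=np.int16)
    s = config.urban_gradient
    if s == 0.0:
        dev_mask = np.zeros(shape, dtype=bool)
        ag_mask = np.zeros(shape, dtype=bool)
        other_mask = np.zeros(shape, dtype=bool)
    else:
        remainder = 1.0 - config.forest_target
        n_dev = int(round(0.55 * s * remainder * ncell))
        n_other = int(round(0.05 * remainder * ncell))
        n_ag = int(round(remainder * ncell)) - n_dev - n_other
        dev_mask = _rank_threshold(urban, np.ones(shape, dtype=bool), n_dev)
        ag_mask = _rank_threshold(ag_field, ~dev_mask, n_ag)
        other_mask = _rank_threshold(other_field, ~dev_mask & ~ag_mask, n_other)

    forest_mask = ~dev_mask & ~ag_mask & ~other_mask

    # developed intensity increases with the urban field (quartiles within class)
    if dev_mask.any():
        u_dev = urban[dev_mask]
        qs = np.quantile(u_dev, [0.4, 0.7, 0.9])
        dev_codes = np.select(
            [u_dev <= qs[0], u_dev <= qs[1], u_dev <= qs[2]],
            [nlcd.DEVELOPED_OPEN, nlcd.DEVELOPED_LOW, nlcd.DEVELOPED_MEDIUM],
            default=nlcd.DEVELOPED_HIGH,
        )
        landcover[dev_mask] = dev_codes
    if ag_mask.any():
        landcover[ag_mask] = np.where(
            ag_field[ag_mask] > np.median(ag_field[ag_mask]),
            nlcd.CULTIVATED_CROPS,
            nlcd.PASTURE_HAY,
        )
    landcover[other_mask] = nlcd.BARREN
    if forest_mask.any():
        f = ftype_field[forest_mask]
        q = np.quantile(f, [0.6, 0.8])
        landcover[forest_mask] = np.select(
            [f <= q[0], f <= q[1]],
            [nlcd.DECIDUOUS_FOREST, nlcd.EVERGREEN_FOREST],
            default=nlcd.MIXED_FOREST,
        )

    # densities rise monotonically along the urban gradient, with noise
    u_std = (urban - urban.mean()) / urban.std()
    pop = 2500.0 * s * expit(2.5 * (u_std - 1.2)) + 8.0
    pop *= np.exp(0.15 * rng.standard_normal(shape))
    housing = pop * 0.42 * np.exp(0.10 * rng.standard_normal(shape))

    return LandscapeStack(
        landcover=landcover,
        pop_density=pop,
        housing_density=housing,
        elevation=elev,
        cell_size=float(config.cell_size),
        origin=(0.0, 0.0),
    )
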