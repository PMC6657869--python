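import numpy as np
import pandas as pd
import pytest

from urbanscale import nlcd
from urbanscale.landscape import LandscapeStack
from urbanscale.metrics import (
    Buffer,
    area_weighted_mean,
    assemble_metrics,
    clumpiness,
    extract_buffer,
    patch_density,
    proportional_cover,
    shannon_diversity,
    surface_range,
    urbanization_pca,
)
from urbanscale.survey import place_count_locations

F = nlcd.DECIDUOUS_FOREST
D = nlcd.DEVELOPED_HIGH


def stack_from(landcover: np.ndarray, cell: float = 30.0) -> LandscapeStack:
    shape = landcover.shape
    return LandscapeStack(
        landcover=landcover.astype(np.int16),
        pop_density=np.zeros(shape),
        housing_density=np.zeros(shape),
        elevation=np.zeros(shape),
        cell_size=cell,
    )


def square_buffer(n: int) -> Buffer:
    """A hand-built buffer whose member set is the full n x n grid."""
    rr, cc = np.mgrid[0:n, 0:n]
    return Buffer(center=(0, 0), radius_m=1.0, rows=rr.ravel(), cols=cc.ravel(), complete=True)


# ------------------------------------------------------------ extraction


def test_tiny_radius_returns_single_cell(mixed_stack):
    buf = extract_buffer(mixed_stack, (4470.0, 4470.0), 10.0)
    assert buf.n_cells == 1
    assert buf.complete
    # even centered on a cell corner, the containing cell is returned
    corner = extract_buffer(mixed_stack, (4500.0, 4500.0), 10.0)
    assert corner.n_cells == 1


def test_edge_disc_flagged_incomplete(mixed_stack):
    buf = extract_buffer(mixed_stack, (100.0, 4500.0), 500.0)
    assert not buf.complete


def test_off_grid_center_errors(mixed_stack):
    with pytest.raises(ValueError, match="off the grid"):
        extract_buffer(mixed_stack, (-50.0, 100.0), 100.0)


def test_member_count_matches_disc_area(mixed_stack):
    # 1 km disc on 60 m cells: count within 1% of pi r^2 / cell area
    buf = extract_buffer(mixed_stack, (4500.0, 4500.0), 1000.0)
    expected = np.pi * 1000.0**2 / mixed_stack.cell_size**2
    assert abs(buf.n_cells - expected) / expected < 0.01


# ----------------------------------------------------------- proportions


def test_uniform_forest_cover_is_one(forest_stack):
    buf = extract_buffer(forest_stack, (1200.0, 1200.0), 400.0)
    assert proportional_cover(buf, forest_stack, nlcd.FOREST) == 1.0
    assert proportional_cover(buf, forest_stack, nlcd.DEVELOPED) == 0.0
    with pytest.raises(ValueError, match="class"):
        proportional_cover(buf, forest_stack, set())


def test_checkerboard_cover_is_half():
    lc = np.where(np.indices((60, 60)).sum(axis=0) % 2 == 0, F, D)
    stack = stack_from(lc)
    buf = extract_buffer(stack, (900.0, 900.0), 600.0)
    assert abs(proportional_cover(buf, stack, {F}) - 0.5) <= 1.0 / buf.n_cells


def test_cover_sums_to_one_over_legend(mixed_stack):
    buf = extract_buffer(mixed_stack, (4500.0, 4000.0), 800.0)
    total = sum(
        proportional_cover(buf, mixed_stack, {code}) for code in nlcd.LEGEND
    )
    assert abs(total - 1.0) < 1e-12


# --------------------------------------------------------- surface means


def test_area_weighted_mean_constant_and_symmetry():
    surface = np.full((40, 40), 7.5)
    stack = stack_from(np.full((40, 40), F))
    buf = extract_buffer(stack, (600.0, 600.0), 300.0)
    assert area_weighted_mean(buf, surface) == pytest.approx(7.5)
    half = np.zeros((40, 40))
    half[:, 20:] = 100.0
    buf2 = square_buffer(40)
    assert area_weighted_mean(buf2, half) == pytest.approx(50.0)
    assert surface_range(buf2, half) == pytest.approx(100.0)


def test_linear_ramp_disc_mean_matches_analytic():
    # mean of a linear surface over a disc equals its value at the center
    n = 101
    ramp = np.tile(np.arange(n, dtype=float), (n, 1))  # f = col index
    stack = stack_from(np.full((n, n), F))
    center = (50.5 * 30.0, 50.5 * 30.0)
    buf = extract_buffer(stack, center, 1200.0)
    assert area_weighted_mean(buf, ramp) == pytest.approx(50.5 - 0.5, rel=0.01)


def test_nan_policy():
    surface = np.full((20, 20), 3.0)
    surface[5, 5] = np.nan
    stack = stack_from(np.full((20, 20), F))
    buf = extract_buffer(stack, (300.0, 300.0), 250.0)
    with pytest.raises(ValueError, match="NaN"):
        area_weighted_mean(buf, surface)
    assert area_weighted_mean(buf, surface, ignore_missing=True) == pytest.approx(3.0)


# -------------------------------------------------------- patch metrics


def flood_fill_count(mask: np.ndarray) -> int:
    """Independent 8-neighbor connected-component count by BFS."""
    seen = np.zeros_like(mask, dtype=bool)
    n = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                n += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            x, y = a + da, b + db
                            if (
                                0 <= x < mask.shape[0]
                                and 0 <= y < mask.shape[1]
                                and mask[x, y]
                                and not seen[x, y]
                            ):
                                seen[x, y] = True
                                stack.append((x, y))
    return n


def test_patch_density_simple_blobs():
    lc = np.full((30, 30), F)
    lc[5:10, 5:10] = D
    stack = stack_from(lc)
    buf = square_buffer(30)
    area_100ha = 30 * 30 * 30.0**2 / 1e6
    assert patch_density(buf, stack, {D}) == pytest.approx(1.0 / area_100ha)
    lc[20:24, 20:24] = D  # second blob, > 1 cell away
    assert patch_density(buf, stack_from(lc), {D}) == pytest.approx(2.0 / area_100ha)
    assert patch_density(buf, stack_from(np.full((30, 30), F)), {D}) == 0.0


def test_patch_density_matches_flood_fill_oracle():
    rng = np.random.default_rng(42)
    buf = square_buffer(30)
    area_100ha = 30 * 30 * 30.0**2 / 1e6
    for _ in range(25):
        mask = rng.random((30, 30)) < rng.uniform(0.2, 0.7)
        lc = np.where(mask, D, F)
        pd_val = patch_density(buf, stack_from(lc), {D})
        assert pd_val == pytest.approx(flood_fill_count(mask) / area_100ha, abs=1e-12)


def clumpy_oracle(mask: np.ndarray) -> float:
    """Brute-force CLUMPY: explicit loop over every rook adjacency."""
    n0, n1 = mask.shape
    g_ii = g_tot = 0
    for i in range(n0):
        for j in range(n1):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, j + dj
                if 0 <= a < n0 and 0 <= b < n1:
                    g_tot += 1
                    if mask[a, b]:
                        g_ii += 1
    area = int(mask.sum())
    p = area / mask.size
    if p == 1.0:
        return 1.0
    nside = int(np.floor(np.sqrt(area)))
    m = area - nside * nside
    min_e = 4 * nside + (0 if m == 0 else (2 if m <= nside else 4))
    denom = g_tot - min_e
    if denom > 0:
        g = g_ii / denom
    elif g_tot > 0:
        g = g_ii / g_tot
    else:
        g = 0.0
    g = min(g, 1.0)
    if g < p and p < 0.5:
        return (g - p) / p
    return (g - p) / (1.0 - p)


def test_checkerboard_clumpiness_is_exactly_minus_one():
    lc = np.where(np.indices((20, 20)).sum(axis=0) % 2 == 0, D, F)
    # even-sided square window: P = 0.5 exactly, no like adjacency
    assert clumpiness(square_buffer(20), stack_from(lc), {D}) == -1.0


def test_uniform_class_clumpiness_is_one(forest_stack):
    buf = extract_buffer(forest_stack, (1200.0, 1200.0), 500.0)
    assert clumpiness(buf, forest_stack, nlcd.FOREST) == 1.0


def test_absent_class_clumpiness_is_missing(forest_stack):
    buf = extract_buffer(forest_stack, (1200.0, 1200.0), 500.0)
    assert np.isnan(clumpiness(buf, forest_stack, {D}))


def test_clumpiness_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    buf = square_buffer(30)
    for _ in range(25):
        mask = rng.random((30, 30)) < rng.uniform(0.15, 0.85)
        if not mask.any():
            continue
        lc = np.where(mask, D, F)
        assert clumpiness(buf, stack_from(lc), {D}) == pytest.approx(
            clumpy_oracle(mask), abs=1e-12
        )


def test_more_patches_at_fixed_p_never_more_clumped():
    # one 6x6 blob vs four scattered 3x3 blobs: same P, fewer adjacencies
    solid = np.full((30, 30), F)
    solid[10:16, 10:16] = D
    spread = np.full((30, 30), F)
    for r, c in ((2, 2), (2, 22), (22, 2), (22, 22)):
        spread[r : r + 3, c : c + 3] = D
    buf = square_buffer(30)
    assert clumpiness(buf, stack_from(solid), {D}) > clumpiness(buf, stack_from(spread), {D})
    assert patch_density(buf, stack_from(spread), {D}) > patch_density(buf, stack_from(solid), {D})


# --------------------------------------------------------------- shannon


def test_shannon_diversity_values(forest_stack):
    buf = extract_buffer(forest_stack, (1200.0, 1200.0), 400.0)
    assert shannon_diversity(buf, forest_stack) == 0.0
    lc = np.where(np.indices((40, 40)).sum(axis=0) % 2 == 0, F, D)
    assert shannon_diversity(square_buffer(40), stack_from(lc)) == pytest.approx(np.log(2))
    # proportions (0.5, 0.3, 0.2) on a hand-built 10-cell buffer
    lc10 = np.array([[F, F, F, F, F, D, D, D, nlcd.PASTURE_HAY, nlcd.PASTURE_HAY]])
    rr = np.zeros(10, dtype=int)
    cc = np.arange(10)
    buf10 = Buffer(center=(0, 0), radius_m=1, rows=rr, cols=cc, complete=True)
    h = shannon_diversity(buf10, stack_from(lc10))
    assert h == pytest.approx(1.0297, abs=5e-5)


# ------------------------------------------------------------------ PCA


def correlated_pair(n: int, r: float, seed: int = 0) -> np.ndarray:
    """Two columns with *exact* sample correlation r (Gram-Schmidt)."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n)
    w = rng.standard_normal(n)
    u = (u - u.mean()) / u.std(ddof=1)
    w = w - w.mean()
    w -= u * (u @ w) / (u @ u)
    w /= w.std(ddof=1)
    v = r * u + np.sqrt(1 - r**2) * w
    return np.column_stack([u, v])


def test_rank_one_pair_gives_eigenvalues_two_zero():
    x = correlated_pair(50, 1.0 - 1e-12)
    pca = urbanization_pca(np.column_stack([x[:, 0], x[:, 0] * 2 + 1]), housing_col=1)
    assert pca.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-9)
    assert pca.n_retained == 1


def test_two_variable_eigenvalues_are_one_plus_minus_r():
    pca = urbanization_pca(correlated_pair(200, 0.5), housing_col=1)
    assert pca.eigenvalues == pytest.approx([1.5, 0.5], abs=1e-9)
    assert pca.n_retained == 1


def test_orthogonal_variables_trigger_fallback_retention():
    # exactly orthonormal columns: correlation = I, no eigenvalue > 1
    rng = np.random.default_rng(3)
    q, _ = np.linalg.qr(rng.standard_normal((60, 6)))
    q = (q - q.mean(axis=0)) / q.std(axis=0, ddof=1)
    q, _ = np.linalg.qr(q - q.mean(axis=0))
    with pytest.warns(UserWarning, match="no eigenvalue"):
        pca = urbanization_pca(q, housing_col=5)
    assert pca.n_retained == 1
    assert pca.eigenvalues.max() <= 1.0 + 1e-9


def test_scores_reproduce_eigenstructure():
    rng = np.random.default_rng(4)
    base = rng.standard_normal((120, 1))
    X = np.hstack([base + 0.5 * rng.standard_normal((120, 1)) for _ in range(6)])
    pca = urbanization_pca(X, housing_col=5)
    assert pca.loadings.T @ pca.loadings == pytest.approx(np.eye(pca.n_retained), abs=1e-9)
    for c in range(pca.n_retained):
        assert pca.scores[:, c].mean() == pytest.approx(0.0, abs=1e-10)
        assert pca.scores[:, c].var(ddof=1) == pytest.approx(pca.eigenvalues[c], abs=1e-9)


def test_constant_variable_named_in_error():
    X = np.column_stack([np.ones(30), np.arange(30.0)])
    with pytest.raises(ValueError, match="v0"):
        urbanization_pca(X, housing_col=1)


def test_housing_orientation_sign():
    X = correlated_pair(100, 0.8, seed=9)
    pca = urbanization_pca(X, housing_col=1)
    assert np.corrcoef(pca.scores[:, 0], X[:, 1])[0, 1] >= 0


# ------------------------------------------------------------- assembly


def test_assemble_bookkeeping_and_forest_recount(mixed_stack):
    design = place_count_locations(mixed_stack, 40, seed=6)
    metrics, pca = assemble_metrics(
        mixed_stack, design, radii_km=[0.2, 0.5], include_patch_metrics=False
    )
    # rows = locations x radii minus border-dropped
    by_r = metrics.groupby("radius_km").size()
    assert (by_r <= 40).all() and (by_r > 0).all()
    # independent forest recount on a sampled row
    row = metrics[metrics.radius_km == 0.5].iloc[3]
    loc = design.locations.set_index("location_id").loc[row.location_id]
    buf = extract_buffer(mixed_stack, (loc.x, loc.y), 500.0)
    vals = mixed_stack.landcover[buf.rows, buf.cols]
    frac = np.isin(vals, list(nlcd.FOREST)).mean()
    assert row.forest_total == pytest.approx(frac, abs=1e-12)
    # covariates carried through
    assert {"observer", "start_time", "julian_date", "landuse_change"} <= set(metrics.columns)


def test_assemble_on_all_forest_stack_reports_missing_scores(forest_stack):
    design = place_count_locations(forest_stack, 12, seed=2)
    metrics, pca = assemble_metrics(
        forest_stack, design, radii_km=[0.2], include_patch_metrics=False
    )
    # constant urbanization surfaces: PCA impossible, scores left missing
    assert metrics["urb1"].isna().all()
    assert pca == {}
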