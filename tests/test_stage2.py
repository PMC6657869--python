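import numpy as np
import pandas as pd
import pytest

from urbanscale.phylo import generate_traits_and_tree, simulate_bm, tree_vcv, yule_tree
from urbanscale.report import load_table1
from urbanscale.stage1 import akaike_weights
from urbanscale.stage2 import (
    build_groups,
    pgls_lambda,
    prepare_responses,
    run_stage2,
    trait_model_average,
    univariate_screen,
)

# ------------------------------------------------------------ responses


def test_inverse_variance_weights():
    df = pd.DataFrame(
        {"species_id": ["a", "b"], "effect": [0.1, 0.2], "se": [0.5, 0.05], "scale_km": [1, 2]}
    )
    _, w, _ = prepare_responses(df)
    assert w["a"] == pytest.approx(4.0)
    assert w["b"] == pytest.approx(400.0)
    assert w["b"] / w["a"] == pytest.approx(100.0)


def test_zero_se_names_species():
    df = pd.DataFrame(
        {"species_id": ["a", "b"], "effect": [0.1, 0.2], "se": [0.5, 0.0], "scale_km": [1, 2]}
    )
    with pytest.raises(ValueError, match="b"):
        prepare_responses(df)


def test_published_table_yields_58_finite_weights():
    _, w, _ = prepare_responses(load_table1())
    assert len(w) == 58
    assert np.isfinite(w).all() and (w > 0).all()


# --------------------------------------------------------------- screen


def test_noise_free_screen_is_one():
    x = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
    assert univariate_screen(x, x * 2.0 + 1.0) == pytest.approx(1.0)


def test_screen_matches_closed_form_arithmetic():
    x = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("abcdef"))
    y = pd.Series([1.1, 1.9, 3.3, 3.7, 5.2, 5.8], index=list("abcdef"))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
    expected = 1 - (1 - r2) * 5 / 4
    assert univariate_screen(x, y) == pytest.approx(expected, abs=1e-12)


def test_constant_trait_screen_is_nan():
    x = pd.Series(np.ones(8), index=[f"s{i}" for i in range(8)])
    y = pd.Series(np.arange(8.0), index=x.index)
    assert np.isnan(univariate_screen(x, y))


def test_too_few_pairs_errors():
    x = pd.Series([1.0, 2, 3], index=list("abc"))
    with pytest.raises(ValueError, match="5"):
        univariate_screen(x, x)


# --------------------------------------------------------------- groups


def make_traits(n=20, missing=None, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"s{i}" for i in range(n)], name="species_id")
    t = pd.DataFrame(
        {"t1": rng.normal(size=n), "t2": rng.normal(size=n), "t3": rng.normal(size=n)},
        index=idx,
    )
    if missing:
        for col, rate in missing.items():
            t.loc[rng.random(n) < rate, col] = np.nan
    return t


def test_no_missing_data_groups_coincide():
    t = make_traits()
    g1, g2 = build_groups(t, {"t1": 0.2, "t2": 0.1, "t3": -0.5}, t.index)
    assert set(g1.species) == set(g2.species)
    assert g1.traits == ["t1", "t2"]
    assert set(g2.traits) == {"t1", "t2", "t3"}


def test_complete_case_count_matches_row_scan():
    t = make_traits(n=200, missing={"t1": 0.2, "t2": 0.2}, seed=3)
    g1, _ = build_groups(t, {"t1": 0.3, "t2": 0.1, "t3": -0.2}, t.index)
    # independent row scan
    expected = sum(
        1
        for s in t.index
        if np.isfinite(t.loc[s, "t1"]) and np.isfinite(t.loc[s, "t2"])
    )
    assert len(g1.species) == expected


def test_correlated_pair_flagged_but_retained():
    rng = np.random.default_rng(4)
    idx = pd.Index([f"s{i}" for i in range(40)])
    a = rng.normal(size=40)
    b = 0.72 * a + np.sqrt(1 - 0.72**2) * rng.normal(size=40)
    t = pd.DataFrame({"t1": a, "t2": b}, index=idx)
    g1, _ = build_groups(t, {"t1": 0.3, "t2": 0.3}, idx)
    assert g1.traits == ["t1", "t2"]
    if g1.flagged_pairs:  # flag emitted when sample |r| crosses 0.70
        assert g1.flagged_pairs[0][:2] == ("t1", "t2")


# ------------------------------------------------------------ averaging


@pytest.fixture(scope="module")
def single_trait_setup():
    rng = np.random.default_rng(5)
    idx = pd.Index([f"s{i}" for i in range(30)], name="species_id")
    t = pd.DataFrame({"t1": rng.normal(size=30)}, index=idx)
    y = pd.Series(0.5 * t["t1"].to_numpy() + rng.normal(0, 0.3, 30), index=idx)
    return y, t


def test_single_trait_two_models_and_k_convention(single_trait_setup):
    y, t = single_trait_setup
    ms = trait_model_average(y, t)
    assert len(ms.all_models) == 2
    ks = dict(zip(ms.all_models.Model, ms.all_models.K))
    assert ks["(intercept)"] == 2
    assert ks["t1"] == 3
    # weights follow from the AIC gap of the two models
    d = ms.all_models.dAIC.to_numpy()
    assert ms.all_models.w.to_numpy() == pytest.approx(akaike_weights(d), abs=1e-12)


def test_selection_table_ordering_and_weight_sum(single_trait_setup):
    y, t = single_trait_setup
    ms = trait_model_average(y, t)
    assert ms.selection_table.dAIC.iloc[0] == 0.0
    assert ms.selection_table.w.sum() == pytest.approx(1.0, abs=1e-12)
    # re-feeding the printed deltas reproduces the weight column at 2 dp
    w2 = akaike_weights(ms.selection_table.dAIC.to_numpy())
    assert np.round(w2, 2) == pytest.approx(np.round(ms.selection_table.w, 2))


def test_equal_weights_match_unweighted_fit(single_trait_setup):
    y, t = single_trait_setup
    w = pd.Series(7.0, index=t.index)
    a = trait_model_average(y, t, weights=w)
    b = trait_model_average(y, t)
    ea = {e.trait: e for e in a.effects}
    eb = {e.trait: e for e in b.effects}
    assert ea["t1"].coef == pytest.approx(eb["t1"].coef, abs=1e-10)
    assert ea["t1"].se == pytest.approx(eb["t1"].se, abs=1e-10)


def test_too_few_species_errors():
    idx = pd.Index([f"s{i}" for i in range(4)])
    t = pd.DataFrame({"t1": [1.0, 2, 3, 4], "t2": [2.0, 1, 4, 3]}, index=idx)
    y = pd.Series([0.1, 0.2, 0.3, 0.4], index=idx)
    with pytest.raises(ValueError, match="too few"):
        trait_model_average(y, t)


# ------------------------------------------------------------------ PGLS


def test_star_phylogeny_reduces_to_ols():
    # star tree: all tips attach directly to the root at equal depth
    import dendropy

    n = 12
    newick = "(" + ",".join(f"S{i:03d}:1.0" for i in range(n)) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    rng = np.random.default_rng(6)
    idx = [f"S{i:03d}" for i in range(n)]
    x = pd.Series(rng.normal(size=n), index=idx)
    y = pd.Series(2.0 * x.to_numpy() + rng.normal(0, 0.1, n), index=idx)
    res = pgls_lambda(x, y, tree)
    assert res.lambda_hat == 0.0
    assert res.p_value == 1.0
    slope = np.polyfit(x.to_numpy(), y.to_numpy(), 1)[0]
    assert res.slope == pytest.approx(slope, abs=1e-8)


def test_lambda_one_brownian_motion_recovered():
    rng = np.random.default_rng(7)
    hats = []
    for _ in range(5):
        tree = yule_tree(64, rng)
        labels, c = tree_vcv(tree)
        y = pd.Series(simulate_bm(c, 1.0, rng)[0], index=labels)
        x = pd.Series(rng.standard_normal(64), index=labels)
        hats.append(pgls_lambda(x, y, tree).lambda_hat)
    assert np.mean(hats) >= 0.8


def test_independent_data_gives_zero_lambda():
    rng = np.random.default_rng(8)
    tree = yule_tree(64, rng)
    labels, _ = tree_vcv(tree)
    x = pd.Series(rng.standard_normal(64), index=labels)
    y = pd.Series(rng.standard_normal(64), index=labels)
    res = pgls_lambda(x, y, tree)
    assert res.lambda_hat < 0.3
    assert res.p_value > 0.05


def test_pgls_requires_enough_tips():
    tree = yule_tree(8, seed=9)
    labels, _ = tree_vcv(tree)
    x = pd.Series([1.0, 2, 3], index=labels[:3])
    y = pd.Series([1.0, 2, 3], index=labels[:3])
    with pytest.raises(ValueError, match="tips"):
        pgls_lambda(x, y, tree)


# ------------------------------------------------------------ end-to-end


def test_run_stage2_recovers_planted_trait_effect():
    traits, tree, truths = generate_traits_and_tree(
        60, seed=10, weights_beta={"granivory": 0.5}, noise_sd=0.1
    )
    resp = pd.DataFrame(
        {
            "species_id": traits.index,
            "effect": [t.beta_true for t in truths],
            "se": 0.1,
            "scale_km": [t.scale_true_km for t in truths],
        }
    )
    result = run_stage2(resp, traits, tree=tree)
    eff = result.effects["effect"].set_index("trait")
    assert "granivory" in eff.index
    assert eff.loc["granivory", "coef"] > 0.2
    # model-selection tables well-formed
    for table in result.selection_tables.values():
        assert table.dAIC.iloc[0] == 0.0
        assert table.w.sum() == pytest.approx(1.0, abs=1e-12)
    # no spurious phylogenetic signal under lambda_true = 0
    assert result.pgls is not None
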