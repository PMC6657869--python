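"""Stage 2: trait effects on effect sizes and scales of effect.

Species-level responses from stage 1 are modeled on traits with all-subsets
weighted Gaussian linear models and AIC averaging. Effect sizes are
inverse-variance weighted (1/SE^2); scales of effect are modeled unweighted
on the km scale. Because traits have missing values, models run in two
groups: (1) traits passing a univariate adjusted-R^2 > 0 screen, restricted
to complete-case species, and (2) traits observed for every species. When a
trait lands in both groups' best-model sets, the larger-magnitude averaged
coefficient is reported.

A univariate PGLS screen (Pagel's lambda by maximum likelihood, LRT against
lambda = 0) checks whether phylogenetic signal would violate the
independence assumption; following standard practice the non-phylogenetic
models proceed when no trait shows significant signal, with a warning
otherwise.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from urbanscale.phylo import lambda_vcv, tree_vcv
from urbanscale.stage1 import DELTA_AIC_MAX, akaike_weights, standardize

log = logging.getLogger(__name__)

TRAIT_CORRELATION_FLAG = 0.70


def prepare_responses(responses: pd.DataFrame) -> tuple[pd.Series, pd.Series, pd.Series]:
    """(effect sizes, inverse-variance weights 1/SE^2, scales of effect),
    indexed by species. Raises if any SE is non-positive."""
    r = responses.set_index("species_id") if "species_id" in responses.columns else responses
    bad = r.index[r["se"] <= 0].tolist()
    if bad:
        raise ValueError(f"non-positive SE for species: {bad}")
    return r["effect"], 1.0 / r["se"] ** 2, r["scale_km"]


# ------------------------------------------------------------------ PGLS


@dataclass
class PhyloSignalResult:
    trait: str
    response: str
    lambda_hat: float
    p_value: float
    slope: float
    n: int


def _gls_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> tuple[float, np.ndarray]:
    n = len(y)
    L = np.linalg.cholesky(V)
    # whiten by the Cholesky factor
    yt = solve_triangular(L, y, lower=True)
    Xt = solve_triangular(L, X, lower=True)
    beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    sigma2 = float(resid @ resid) / n
    logdet = 2.0 * np.log(np.diag(L)).sum()
    llf = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return llf, beta


def pgls_lambda(
    trait: pd.Series,
    response: pd.Series,
    tree: dendropy.Tree,
    trait_name: str | None = None,
    response_name: str = "effect",
) -> PhyloSignalResult:
    """Univariate GLS regression of response on trait under V(lambda), with
    Pagel's lambda estimated by maximum likelihood on [0, 1] and a
    likelihood-ratio p against lambda = 0 (chi^2_1 halved at the boundary).

    On a star phylogeny (no shared history) lambda is unidentified and is
    reported as 0 with p = 1.
    """
    labels, c = tree_vcv(tree)
    common = [
        s
        for s in labels
        if s in trait.index
        and s in response.index
        and np.isfinite(trait[s])
        and np.isfinite(response[s])
    ]
    if len(common) < 5:
        raise ValueError(f"fewer than 5 usable tips ({len(common)})")
    idx = [labels.index(s) for s in common]
    c = c[np.ix_(idx, idx)]
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)  # correlation scale; diagonal 1
    y = response.loc[common].to_numpy(dtype=float)
    x = trait.loc[common].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), x])
    name = trait_name or (trait.name if trait.name is not None else "trait")

    off_diag = c - np.diag(np.diag(c))
    if np.abs(off_diag).max() < 1e-10:
        _, beta = _gls_loglik(y, X, np.eye(len(y)))
        return PhyloSignalResult(name, response_name, 0.0, 1.0, float(beta[1]), len(y))

    def negll(lam: float) -> float:
        return -_gls_loglik(y, X, lambda_vcv(c, lam))[0]

    res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded")
    cands = [(0.0, negll(0.0)), (1.0, negll(1.0)), (float(res.x), float(res.fun))]
    lam_hat, nll_hat = min(cands, key=lambda t: t[1])
    ll0 = -negll(0.0)
    lr = 2.0 * ((-nll_hat) - ll0)
    p = 1.0 if lr <= 1e-12 else 0.5 * float(chi2.sf(lr, df=1))
    _, beta = _gls_loglik(y, X, lambda_vcv(c, lam_hat))
    return PhyloSignalResult(name, response_name, lam_hat, p, float(beta[1]), len(y))


# ------------------------------------------------------------- screening


def univariate_screen(trait: pd.Series, response: pd.Series, weights: pd.Series | None = None):
    """Adjusted R^2 of the (weighted) simple linear regression of the
    response on one trait: ``1 - (1 - R^2)(n-1)/(n-2)``. Returns NaN for a
    constant trait (excluded with reason logged)."""
    df = pd.DataFrame({"x": trait, "y": response}).dropna()
    if len(df) < 5:
        raise ValueError(f"fewer than 5 non-missing pairs for trait {trait.name!r}")
    if df["x"].nunique() == 1:
        log.info("trait %r is constant among scored species; excluded", trait.name)
        return float("nan")
    w = np.ones(len(df)) if weights is None else weights.loc[df.index].to_numpy(dtype=float)
    res = sm.WLS(df["y"], sm.add_constant(df["x"]), weights=w).fit()
    n = len(df)
    return float(1.0 - (1.0 - res.rsquared) * (n - 1) / (n - 2))


@dataclass
class TraitGroup:
    """One modeling group: the traits in it and the species usable with it."""

    name: str
    traits: list[str]
    species: list[str]
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)


def build_groups(
    traits: pd.DataFrame,
    screen: dict[str, float],
    response_index: pd.Index,
    corr_threshold: float = TRAIT_CORRELATION_FLAG,
) -> tuple[TraitGroup, TraitGroup]:
    """(group 1: screened traits with complete-case species, group 2: traits
    with values for all species). Pairwise trait correlations >= 0.70 are
    flagged but the traits are retained."""
    t = traits.loc[traits.index.intersection(response_index)]
    g1_traits = [name for name, r2 in screen.items() if np.isfinite(r2) and r2 > 0]
    g1_species = t.index[t[g1_traits].notna().all(axis=1)].tolist() if g1_traits else []
    g2_traits = [c for c in t.columns if t[c].notna().all()]
    g2_species = t.index.tolist()
    if not g1_traits and not g2_traits:
        raise ValueError("both trait groups are empty")

    def flags(cols: list[str], species: list[str]):
        out = []
        if len(cols) < 2:
            return out
        corr = t.loc[species, cols].corr()
        for a, b in itertools.combinations(cols, 2):
            r = float(corr.loc[a, b])
            if abs(r) >= corr_threshold:
                out.append((a, b, r))
                log.warning("traits %r and %r correlated (|r| = %.2f); both retained", a, b, abs(r))
        return out

    g1 = TraitGroup("screened", g1_traits, g1_species, flags(g1_traits, g1_species))
    g2 = TraitGroup("complete", g2_traits, g2_species, flags(g2_traits, g2_species))
    return g1, g2


# ------------------------------------------------------------- averaging


@dataclass
class TraitEffect:
    trait: str
    response: str
    coef: float
    se: float
    group: str
    in_best_models: bool


@dataclass
class TraitModelSet:
    """All-subsets results for one (response, trait group) pair."""

    effects: list[TraitEffect]
    selection_table: pd.DataFrame  # best (delta <= 2) models: Model, K, AIC, dAIC, w
    all_models: pd.DataFrame


def trait_model_average(
    response: pd.Series,
    traits: pd.DataFrame,
    weights: pd.Series | None = None,
    group_name: str = "",
    response_name: str = "effect",
    delta_max: float = DELTA_AIC_MAX,
) -> TraitModelSet:
    """All-subsets weighted Gaussian linear models over a trait group with
    full AIC averaging.

    Traits are partial-SD divided and standardized first. AIC counts
    K = coefficients + intercept + error SD, so an intercept-only model has
    K = 2 and a one-trait model K = 3. Per-trait averaged coefficients use
    the delta <= 2 set with renormalized weights and zero coefficients for
    models lacking the trait; the unconditional SE adds between-model
    spread.
    """
    common = traits.dropna().index.intersection(response.dropna().index)
    y = response.loc[common].to_numpy(dtype=float)
    names = list(traits.columns)
    n, p = len(common), len(names)
    if n <= p + 2:
        raise ValueError(f"n = {n} species too few for {p} traits")
    design = standardize(traits.loc[common])
    Z = design.Z
    w = np.ones(n) if weights is None else weights.loc[common].to_numpy(dtype=float)

    records = []
    for r in range(p + 1):
        for combo in itertools.combinations(names, r):
            X = sm.add_constant(Z[list(combo)], has_constant="add")
            fit = sm.WLS(y, X, weights=w).fit()
            k = len(combo) + 2  # coefficients + intercept + error SD
            aic = -2.0 * fit.llf + 2.0 * k
            records.append(
                {
                    "terms": combo,
                    "k": k,
                    "aic": aic,
                    "coefs": {t: float(fit.params[t]) for t in combo},
                    "vars": {t: float(fit.cov_params().loc[t, t]) for t in combo},
                }
            )
    aics = np.array([r["aic"] for r in records])
    deltas = aics - aics.min()
    ws = akaike_weights(deltas)
    order = np.argsort(deltas, kind="stable")

    best_idx = [i for i in order if deltas[i] <= delta_max]
    w_best = akaike_weights(deltas[best_idx])
    effects = []
    for trait in names:
        betas = np.array([records[i]["coefs"].get(trait, 0.0) for i in best_idx])
        varis = np.array([records[i]["vars"].get(trait, 0.0) for i in best_idx])
        beta_bar = float(w_best @ betas)
        se = float(w_best @ np.sqrt(varis + (betas - beta_bar) ** 2))
        included = any(trait in records[i]["terms"] for i in best_idx)
        effects.append(TraitEffect(trait, response_name, beta_bar, se, group_name, included))

    def label(terms) -> str:
        return " + ".join(terms) if terms else "(intercept)"

    all_models = pd.DataFrame(
        {
            "Model": [label(records[i]["terms"]) for i in order],
            "K": [records[i]["k"] for i in order],
            "AIC": aics[order],
            "dAIC": deltas[order],
            "w": ws[order],
        }
    )
    sel = all_models[all_models.dAIC <= delta_max].copy()
    sel["w"] = akaike_weights(sel["dAIC"].to_numpy())
    return TraitModelSet(effects=effects, selection_table=sel.reset_index(drop=True), all_models=all_models)


def combine_group_effects(sets: list[TraitModelSet]) -> pd.DataFrame:
    """Final per-trait effect across groups: the larger-magnitude averaged
    coefficient when a trait appears in more than one group's best-model
    set; traits absent from every best-model set are not reported."""
    rows: dict[str, TraitEffect] = {}
    for s in sets:
        for e in s.effects:
            if not e.in_best_models:
                continue
            if e.trait not in rows or abs(e.coef) > abs(rows[e.trait].coef):
                rows[e.trait] = e
    return pd.DataFrame(
        [
            {
                "trait": e.trait,
                "response": e.response,
                "coef": e.coef,
                "se": e.se,
                "group": e.group,
            }
            for e in rows.values()
        ]
    ).sort_values("coef", ascending=False, ignore_index=True) if rows else pd.DataFrame(
        columns=["trait", "response", "coef", "se", "group"]
    )


# ---------------------------------------------------------------- driver


@dataclass
class Stage2Result:
    effects: dict[str, pd.DataFrame]  # response -> final TraitEffect table
    selection_tables: dict[tuple[str, str], pd.DataFrame]  # (response, group)
    screen: pd.DataFrame
    pgls: pd.DataFrame | None = None


def run_stage2(
    responses: pd.DataFrame,
    traits: pd.DataFrame,
    tree: dendropy.Tree | None = None,
    alpha: float = 0.05,
    delta_max: float = DELTA_AIC_MAX,
) -> Stage2Result:
    """Full stage 2: PGLS screen (when a tree is supplied), univariate
    adjusted-R^2 screening, two-group all-subsets averaging, and the
    cross-group combination rule, for both responses (effect size, scale of
    effect)."""
    effect, wts, scale = prepare_responses(responses)
    traits = traits.loc[traits.index.intersection(effect.index)]

    pgls_rows = []
    if tree is not None:
        for resp_name, resp in (("effect", effect), ("scale", scale)):
            for trait in traits.columns:
                try:
                    r = pgls_lambda(traits[trait], resp, tree, trait_name=trait, response_name=resp_name)
                except ValueError as exc:
                    log.info("PGLS skipped for %s/%s: %s", trait, resp_name, exc)
                    continue
                pgls_rows.append(
                    {
                        "trait": r.trait,
                        "response": r.response,
                        "lambda": r.lambda_hat,
                        "p": r.p_value,
                        "n": r.n,
                    }
                )
        sig = [r for r in pgls_rows if r["p"] < alpha]
        if sig:
            warnings.warn(
                "phylogenetic signal detected for "
                + ", ".join(f"{r['trait']}/{r['response']}" for r in sig)
                + "; proceeding non-phylogenetically",
                stacklevel=2,
            )

    screen_rows = []
    effects: dict[str, pd.DataFrame] = {}
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for resp_name, resp, w in (("effect", effect, wts), ("scale", scale, None)):
        screen: dict[str, float] = {}
        for trait in traits.columns:
            try:
                r2 = univariate_screen(traits[trait], resp, w)
            except ValueError:
                r2 = float("nan")
            screen[trait] = r2
            screen_rows.append({"response": resp_name, "trait": trait, "adj_r2": r2})
        g1, g2 = build_groups(traits, screen, resp.index)
        sets = []
        for g in (g1, g2):
            if not g.traits or len(g.species) <= len(g.traits) + 2:
                log.warning("group %r unusable for %s (traits=%d, species=%d)",
                            g.name, resp_name, len(g.traits), len(g.species))
                continue
            ms = trait_model_average(
                resp.loc[g.species],
                traits.loc[g.species, g.traits],
                weights=w.loc[g.species] if w is not None else None,
                group_name=g.name,
                response_name=resp_name,
                delta_max=delta_max,
            )
            sets.append(ms)
            tables[(resp_name, g.name)] = ms.selection_table
        effects[resp_name] = combine_group_effects(sets)
    return Stage2Result(
        effects=effects,
        selection_tables=tables,
        screen=pd.DataFrame(screen_rows),
        pgls=pd.DataFrame(pgls_rows) if pgls_rows else None,
    )
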