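"""Stage 1: per-species, per-radius all-subsets logistic inference.

For each species and each landscape radius, every subset of the candidate
predictors (plus the intercept-only model) is fit by maximum-likelihood
logistic regression. The urbanization coefficient is *full* model-averaged
over the ``deltaAIC <= 2`` set -- models lacking the term contribute a zero
coefficient -- with an unconditional standard error that adds between-model
spread to within-model sampling variance. The species' scale of effect is
the radius with the largest absolute averaged coefficient.

Predictors are divided by their partial standard deviations (SD shrunk by
the variance inflation factor and a degrees-of-freedom factor) and then
standardized, so coefficients are comparable across models and species.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import gaussian_kde
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

log = logging.getLogger(__name__)

MAX_SUBSET_PREDICTORS = 15
CORRELATION_FLAG = 0.70
DELTA_AIC_MAX = 2.0


# ---------------------------------------------------------------- scaling


def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor 1/(1-R^2_j) per column of ``X``.

    R^2_j comes from the OLS regression of column j on the remaining
    columns (with intercept). A single column has VIF 1.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    out = np.ones(p)
    if p == 1:
        return out
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        xj = X[:, j]
        coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        sst = ((xj - xj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst
        if r2 > 1 - 1e-10:
            partner = int(np.argmax(np.abs(np.corrcoef(X.T)[j]) - np.eye(p)[j]))
            raise ValueError(
                f"perfect collinearity: column {j} is determined by the others "
                f"(most correlated with column {partner})"
            )
        out[j] = 1.0 / (1.0 - r2)
    return out


def partial_sd(X, col: int | str | None = None) -> np.ndarray | float:
    """Partial standard deviation(s): ``s_j * sqrt(1/VIF_j) * sqrt((n-1)/(n-p))``.

    ``X`` is the full predictor matrix (the VIF of each column is computed
    against all the others). Returns the vector of partial SDs, or a single
    value when ``col`` is given.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = list(range(arr.shape[1]))
    n, p = arr.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    s = arr.std(axis=0, ddof=1)
    for j, sd in enumerate(s):
        if sd == 0:
            raise ValueError(f"column {names[j]!r} is constant")
    psd = s * np.sqrt(1.0 / vif(arr)) * np.sqrt((n - 1) / (n - p))
    if col is None:
        return psd
    j = names.index(col) if isinstance(col, str) else int(col)
    return float(psd[j])


@dataclass
class StandardizedDesign:
    """Predictors after partial-SD division and standardization.

    Columns of ``Z`` have mean 0 and unit variance. ``centers`` and
    ``scales`` invert the whole transform:
    ``X = Z * scales * partial_sds + centers`` with centers on the
    partial-SD-divided scale times partial SD... see
    :meth:`inverse_transform` for the exact round trip.
    """

    Z: pd.DataFrame
    partial_sds: np.ndarray
    centers: np.ndarray  # means of X / partial_sd
    scales: np.ndarray  # SDs of X / partial_sd
    vifs: np.ndarray
    n: int
    p: int

    def inverse_transform(self) -> pd.DataFrame:
        x = (self.Z.to_numpy() * self.scales + self.centers) * self.partial_sds
        return pd.DataFrame(x, columns=self.Z.columns, index=self.Z.index)


def standardize(X) -> StandardizedDesign:
    """Divide each column by its partial SD, then center and scale to unit
    variance (ddof=1). Transformation parameters are stored so the input can
    be recovered."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    arr = X.to_numpy(dtype=float)
    n, p = arr.shape
    psd = partial_sd(X)
    vifs = vif(arr)
    div = arr / psd
    centers = div.mean(axis=0)
    scales = div.std(axis=0, ddof=1)
    z = (div - centers) / scales
    return StandardizedDesign(
        Z=pd.DataFrame(z, columns=X.columns, index=X.index),
        partial_sds=psd,
        centers=centers,
        scales=scales,
        vifs=vifs,
        n=n,
        p=p,
    )


# ---------------------------------------------------------------- fitting


@dataclass
class LogisticFit:
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    aic: float
    k: int
    separated: bool = False


def fit_logistic(y, X) -> LogisticFit:
    """Maximum-likelihood logistic fit; AIC = -2*llf + 2*K, K counting the
    intercept. Complete separation is flagged (``separated=True``) rather
    than raising, so callers can drop the model from a candidate set."""
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("response takes a single value; cannot fit")
    if isinstance(X, pd.DataFrame):
        Xc = sm.add_constant(X.astype(float), has_constant="add")
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            X = X.T
        Xc = sm.add_constant(pd.DataFrame(X), has_constant="add")
    k = Xc.shape[1]
    if len(y) <= k:
        raise ValueError(f"n={len(y)} too small for K={k} parameters")
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
            separated = True
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return LogisticFit(
            params=pd.Series(np.nan, index=Xc.columns),
            cov=pd.DataFrame(np.nan, index=Xc.columns, columns=Xc.columns),
            llf=np.nan,
            aic=np.nan,
            k=k,
            separated=True,
        )
    aic = -2.0 * res.llf + 2.0 * k
    return LogisticFit(
        params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=Xc.columns, columns=Xc.columns),
        llf=float(res.llf),
        aic=float(aic),
        k=k,
        separated=separated,
    )


@dataclass
class CandidateModel:
    """One fitted predictor subset in an AIC candidate set."""

    terms: tuple[str, ...]
    k: int
    aic: float
    delta: float = np.nan
    weight: float = np.nan
    beta_urb: float = 0.0  # 0 when the urbanization term is absent
    var_urb: float = 0.0


def all_subsets(
    y,
    design: StandardizedDesign | pd.DataFrame,
    urb_col: str = "urb1",
    term_groups: dict[str, list[str]] | None = None,
    cap: int = MAX_SUBSET_PREDICTORS,
    forced: tuple[str, ...] = (),
) -> list[CandidateModel]:
    """Fit every predictor-subset logistic model (2^p, intercept-only
    included).

    ``term_groups`` maps a term name to the design columns it spans
    (categorical indicator blocks enter or leave subsets as a unit);
    unlisted columns are their own term. ``forced`` terms appear in every
    model. Complete-separation fits are dropped from the candidate set with
    a log entry. Deltas and Akaike weights are filled over the returned set.
    """
    Z = design.Z if isinstance(design, StandardizedDesign) else design
    groups = dict(term_groups or {})
    grouped_cols = {c for cols in groups.values() for c in cols}
    for c in Z.columns:
        if c not in grouped_cols:
            groups[c] = [c]
    free = [t for t in groups if t not in forced]
    if len(free) + len(forced) > cap:
        raise ValueError(
            f"{len(free) + len(forced)} terms exceed the subset cap ({cap}); "
            "reduce predictors or raise the cap"
        )
    _screen_correlations(Z)

    models: list[CandidateModel] = []
    n_dropped = 0
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            terms = tuple(forced) + combo
            cols = [c for t in terms for c in groups[t]]
            fit = fit_logistic(y, Z[cols]) if cols else fit_logistic(
                y, pd.DataFrame(index=Z.index)
            )
            if fit.separated:
                n_dropped += 1
                continue
            beta = float(fit.params.get(urb_col, 0.0))
            var = float(fit.cov.loc[urb_col, urb_col]) if urb_col in cols else 0.0
            models.append(
                CandidateModel(terms=terms, k=fit.k, aic=fit.aic, beta_urb=beta, var_urb=var)
            )
    if n_dropped:
        log.info("dropped %d completely separated fits from the candidate set", n_dropped)
    if not models:
        raise RuntimeError("every candidate model was dropped (complete separation)")
    best = min(m.aic for m in models)
    deltas = [m.aic - best for m in models]
    ws = akaike_weights(deltas)
    for m, d, w in zip(models, deltas, ws):
        m.delta = d
        m.weight = w
    models.sort(key=lambda m: m.delta)
    return models


def _screen_correlations(Z: pd.DataFrame, threshold: float = CORRELATION_FLAG) -> None:
    num = Z.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        return
    corr = num.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.argmax(corr), corr.shape)
    if corr[i, j] >= threshold:
        warnings.warn(
            f"predictors {num.columns[i]!r} and {num.columns[j]!r} are correlated "
            f"(|r| = {corr[i, j]:.2f} >= {threshold}); coefficients may be unstable",
            stacklevel=3,
        )


def akaike_weights(deltas) -> np.ndarray:
    """``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)`` over the given set."""
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ValueError("empty candidate set")
    if (d < -1e-9).any():
        raise ValueError("deltas must be non-negative")
    w = np.exp(-d / 2.0)
    return w / w.sum()


# ----------------------------------------------------------- averaging


@dataclass
class ModelAverage:
    beta: float
    se: float
    unimodal: bool
    n_models: int


def _is_unimodal(betas: np.ndarray, weights: np.ndarray) -> bool:
    """Single local maximum of the weighted Gaussian KDE (Silverman
    bandwidth) of the candidate coefficients; <= 2 models are unimodal by
    definition."""
    if len(betas) <= 2 or np.ptp(betas) < 1e-12:
        return True
    kde = gaussian_kde(betas, bw_method="silverman", weights=weights)
    h = kde.factor * betas.std(ddof=1)
    grid = np.linspace(betas.min() - 3 * h, betas.max() + 3 * h, 512)
    dens = kde(grid)
    interior = dens[1:-1]
    n_max = int(np.sum((interior > dens[:-2]) & (interior >= dens[2:])))
    return n_max <= 1


def model_average(candidates: list[CandidateModel], delta_max: float = DELTA_AIC_MAX) -> ModelAverage:
    """Full model averaging of the urbanization coefficient over the
    ``delta <= delta_max`` set with weights renormalized over that set.

    ``beta_bar = sum w_i beta_i`` (zero for models lacking the term) and the
    unconditional SE is ``sum w_i sqrt(var_i + (beta_i - beta_bar)^2)``.
    """
    best = [m for m in candidates if m.delta <= delta_max]
    if not best:
        raise ValueError("no candidate with delta <= delta_max (the best model always qualifies)")
    w = akaike_weights([m.delta - min(m.delta for m in best) for m in best])
    betas = np.array([m.beta_urb for m in best])
    varis = np.array([m.var_urb for m in best])
    beta_bar = float(w @ betas)
    se = float(w @ np.sqrt(varis + (betas - beta_bar) ** 2))
    return ModelAverage(
        beta=beta_bar,
        se=se,
        unimodal=_is_unimodal(betas, w),
        n_models=len(best),
    )


def scale_of_effect(per_radius: dict[float, ModelAverage]) -> tuple[float, ModelAverage] | None:
    """Radius with the largest |averaged coefficient| among unimodal radii;
    ties go to the smallest radius. ``None`` when every radius is excluded."""
    usable = [(r, ma) for r, ma in sorted(per_radius.items()) if ma.unimodal]
    if not usable:
        return None
    best_r, best_ma = usable[0]
    for r, ma in usable[1:]:
        if abs(ma.beta) > abs(best_ma.beta) + 1e-15:
            best_r, best_ma = r, ma
    return best_r, best_ma


# ---------------------------------------------------------------- driver


@dataclass
class Stage1Result:
    """Outputs of the stage-1 run.

    ``responses`` is in the per-species summary layout (species_id, n,
    effect, se, scale_km); ``per_radius`` holds every (species, radius)
    averaged coefficient; ``candidates`` keeps the full candidate sets.
    """

    responses: pd.DataFrame
    per_radius: pd.DataFrame
    candidates: dict[tuple[str, float], list[CandidateModel]] = field(default_factory=dict)


GENERIC_FOREST_PREDICTORS = ("forest", "pd", "clumpy")
CATEGORICAL_COVARIATES = ("observer", "year", "dominant_habitat")


def _resolve_predictors(predictors, group: str) -> list[str]:
    return [f"{p}_{group}" if p in GENERIC_FOREST_PREDICTORS else p for p in predictors]


def run_stage1(
    metrics: pd.DataFrame,
    detections,
    predictors: list[str],
    urb_col: str = "urb1",
    radii_km=None,
    species_forest_group: dict[str, str] | None = None,
    allowed_locations: dict[str, set] | None = None,
    cap: int = MAX_SUBSET_PREDICTORS,
    delta_max: float = DELTA_AIC_MAX,
    forced: tuple[str, ...] = (),
) -> Stage1Result:
    """Run stage 1 for every species in a detection table.

    ``predictors`` may use the generic names ``forest``, ``pd``, ``clumpy``;
    these resolve per species via ``species_forest_group`` (default
    ``total``, the all-forest-classes fallback). Categorical covariates
    among the predictors enter as treatment-coded indicator blocks that are
    kept out of the partial-SD standardization. ``allowed_locations``
    restricts each species to locations inside its range.
    """
    det = detections.table if hasattr(detections, "table") else detections
    radii = sorted(radii_km) if radii_km is not None else sorted(metrics["radius_km"].unique())
    groups_map = species_forest_group or {}

    resp_rows, radius_rows = [], []
    candidates: dict[tuple[str, float], list[CandidateModel]] = {}
    for species_id, sdet in det.groupby("species_id"):
        group = groups_map.get(species_id, "total")
        cols = _resolve_predictors(predictors, group)
        missing_cols = [c for c in cols if c not in metrics.columns and c not in CATEGORICAL_COVARIATES]
        if missing_cols:
            fallback = _resolve_predictors(predictors, "total")
            log.warning(
                "species %s: no metrics for forest group %r (missing %s); using total forest",
                species_id,
                group,
                missing_cols,
            )
            cols = fallback
        sdet = sdet.set_index("location_id")["detected"]
        if allowed_locations and species_id in allowed_locations:
            sdet = sdet[sdet.index.isin(allowed_locations[species_id])]

        per_radius: dict[float, ModelAverage] = {}
        n_at_radius: dict[float, int] = {}
        for radius in radii:
            m = metrics[metrics.radius_km == radius].set_index("location_id")
            common = m.index.intersection(sdet.index)
            m = m.loc[common]
            y = sdet.loc[common].to_numpy()
            if len(np.unique(y)) < 2 or len(y) < 10:
                log.info("species %s radius %s: response degenerate; skipped", species_id, radius)
                continue
            cont = [c for c in cols if c not in CATEGORICAL_COVARIATES]
            X = m[cont].astype(float)
            if X.isna().any().any():
                keep = ~X.isna().any(axis=1)
                X, y = X[keep], y[keep.to_numpy()]
            try:
                design = standardize(X)
            except ValueError as exc:
                log.warning("species %s radius %s: %s; radius skipped", species_id, radius, exc)
                continue
            Z = design.Z
            term_groups = None
            cat = [c for c in cols if c in CATEGORICAL_COVARIATES]
            if cat:
                dummies = pd.get_dummies(m[cat].astype(str), drop_first=True, dtype=float)
                dummies = dummies.loc[Z.index]
                term_groups = {
                    c: [d for d in dummies.columns if d.startswith(f"{c}_")] for c in cat
                }
                Z = pd.concat([Z, dummies], axis=1)
            cand = all_subsets(y, Z, urb_col=urb_col, term_groups=term_groups, cap=cap, forced=forced)
            candidates[(species_id, radius)] = cand
            ma = model_average(cand, delta_max=delta_max)
            per_radius[radius] = ma
            n_at_radius[radius] = len(y)
            radius_rows.append(
                {
                    "species_id": species_id,
                    "radius_km": radius,
                    "effect": ma.beta,
                    "se": ma.se,
                    "unimodal": ma.unimodal,
                    "n_models": ma.n_models,
                    "n": len(y),
                }
            )
        sel = scale_of_effect(per_radius)
        if sel is None:
            log.warning("species %s: no usable radius (all excluded); species dropped", species_id)
            continue
        radius, ma = sel
        resp_rows.append(
            {
                "species_id": species_id,
                "n": n_at_radius[radius],
                "effect": ma.beta,
                "se": ma.se,
                "scale_km": radius,
            }
        )
    return Stage1Result(
        responses=pd.DataFrame(resp_rows),
        per_radius=pd.DataFrame(radius_rows),
        candidates=candidates,
    )
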