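"""Phylogenies, trait evolution and trait-driven ground truth.

Traits evolve on a Yule (pure-birth) tree under lambda-scaled Brownian
motion: the Brownian tip covariance has its off-diagonal entries multiplied
by Pagel's lambda, so lambda = 0 gives i.i.d. tips and lambda = 1 plain
Brownian motion. Binary traits threshold a latent continuous character.
Each species' true urbanization coefficient and true scale of effect are
linear combinations of its standardized trait latents plus Gaussian noise;
the scale is snapped (on a log axis) to the nearest configured radius so
scale recovery has an exact answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import norm

from urbanscale.survey import TruthRecord

DEFAULT_RADII_KM = (0.2, 0.5, 1, 2, 4, 6, 8, 10, 12, 16)


@dataclass
class TraitSpec:
    """One trait's generating distribution.

    ``kind`` is ``continuous`` (value = loc + scale * latent, floored at
    ``minimum``) or ``binary`` (latent thresholded at the standard-normal
    quantile of 1 - prevalence).
    """

    name: str
    kind: str = "continuous"
    loc: float = 0.0
    scale: float = 1.0
    prevalence: float = 0.3
    minimum: float = 0.0
    missing_rate: float = 0.0


def default_trait_specs(missing_rate: float = 0.0) -> list[TraitSpec]:
    """A realistic forest-passerine trait roster."""
    cont = [
        ("wingspan_cm", 25.0, 8.0),
        ("body_mass_g", 30.0, 15.0),
        ("clutch_size", 4.0, 1.0),
        ("fledglings_per_clutch", 3.0, 1.0),
        ("duration_in_nest_d", 14.0, 4.0),
        ("flock_size", 6.0, 4.0),
        ("lifespan_y", 8.0, 3.0),
        ("foraging_height_m", 6.0, 4.0),
        ("nesting_height_m", 5.0, 3.0),
    ]
    binary = [
        ("frugivory", 0.3),
        ("granivory", 0.3),
        ("omnivory", 0.35),
        ("cavity_nesting", 0.25),
        ("resident", 0.4),
    ]
    specs = [
        TraitSpec(name, "continuous", loc, scale, minimum=0.1 * loc, missing_rate=missing_rate)
        for name, loc, scale in cont
    ]
    specs += [
        TraitSpec(name, "binary", prevalence=prev, missing_rate=missing_rate)
        for name, prev in binary
    ]
    return specs


class _Lineage:
    __slots__ = ("birth", "children", "split")

    def __init__(self, birth: float):
        self.birth = birth
        self.children: list[_Lineage] | None = None
        self.split = np.nan


def yule_tree(n_tips: int, seed, birth_rate: float = 1.0) -> dendropy.Tree:
    """Simulate an ultrametric pure-birth tree with ``n_tips`` extant tips.

    Waiting times between speciations are Exp(k * birth_rate) with k the
    current lineage count; the splitting lineage is uniform among active
    ones. Taxa are labeled ``S000 .. S{n-1}``. All branch lengths are
    positive with probability one.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = 0.0
    root = _Lineage(0.0)
    active = [root]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        node.split = t
        node.children = [_Lineage(t), _Lineage(t)]
        active.extend(node.children)
    t_end = t + rng.exponential(1.0 / (len(active) * birth_rate))

    labels = iter([f"S{i:03d}" for i in range(n_tips)])

    def newick(node: _Lineage) -> str:
        if node.children is None:
            return f"{next(labels)}:{t_end - node.birth:.10f}"
        left, right = (newick(c) for c in node.children)
        return f"({left},{right}):{node.split - node.birth:.10f}"

    return dendropy.Tree.get(data=newick(root) + ";", schema="newick")


def tree_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion tip covariance: C[i, j] is the root-to-MRCA path
    length of tips i and j (root-to-tip depth on the diagonal)."""
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    index = {lbl: i for i, lbl in enumerate(labels)}
    n = len(labels)
    c = np.zeros((n, n))
    depth: dict = {tree.seed_node: tree.seed_node.edge.length or 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    leafsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            c[i, i] = depth[node]
            leafsets[node] = [i]
        else:
            children = [leafsets.pop(ch) for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            c[i, j] = c[j, i] = d
            leafsets[node] = [i for ch in children for i in ch]
    return labels, c


def lambda_vcv(c: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariance by Pagel's lambda, diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    v = lam * c
    np.fill_diagonal(v, np.diag(c))
    return v


def simulate_bm(c: np.ndarray, lam: float, rng: np.random.Generator, n_traits: int = 1) -> np.ndarray:
    """Draw ``n_traits`` independent unit-variance characters under V(lambda).

    The covariance is first normalized to unit diagonal so latents are
    directly comparable across trees.
    """
    d = np.sqrt(np.diag(c))
    cn = c / np.outer(d, d)
    v = lambda_vcv(cn, lam)
    chol = np.linalg.cholesky(v + 1e-10 * np.eye(len(v)))
    return (chol @ rng.standard_normal((len(v), n_traits))).T


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_traits_and_tree(
    n_species: int,
    seed: int,
    trait_specs: list[TraitSpec] | None = None,
    lambda_true: float = 0.0,
    weights_beta: dict[str, float] | None = None,
    weights_scale: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    beta_mean: float = -0.36,
    scale_center_km: float = 1.5,
    radii_km=DEFAULT_RADII_KM,
) -> tuple[pd.DataFrame, dendropy.Tree, list[TruthRecord]]:
    """Generate a trait table, a Yule tree, and per-species ground truth.

    ``weights_beta`` / ``weights_scale`` give each trait's linear effect on
    the true urbanization coefficient (log-odds per SD) and on the log2 of
    the true scale of effect (km); effects apply to *standardized* trait
    latents, and Gaussian noise with ``noise_sd`` is added to both. The
    noisy log2 scale is snapped to the nearest radius in ``radii_km``.
    Missing values (MCAR, per-trait rates from the specs) are punched into
    the returned table only -- the truth is computed from complete latents.
    """
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must be in [0, 1]")
    specs = trait_specs if trait_specs is not None else default_trait_specs()
    weights_beta = weights_beta or {}
    weights_scale = weights_scale or {}
    unknown = (set(weights_beta) | set(weights_scale)) - {s.name for s in specs}
    if unknown:
        raise ValueError(f"trait-effect weights name unknown traits: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    tree = yule_tree(n_species, rng)
    labels, c = tree_vcv(tree)
    latents = simulate_bm(c, lambda_true, rng, n_traits=len(specs))

    values: dict[str, np.ndarray] = {}
    zs: dict[str, np.ndarray] = {}
    for spec, latent in zip(specs, latents):
        if spec.kind == "binary":
            values[spec.name] = (latent > norm.ppf(1 - spec.prevalence)).astype(float)
        else:
            values[spec.name] = np.maximum(spec.loc + spec.scale * latent, spec.minimum)
        # effects act on the *observed* trait, standardized, so stated
        # weights are per-SD effects recoverable by the trait models
        zs[spec.name] = _zscore(values[spec.name])

    beta_true = beta_mean + rng.normal(0.0, noise_sd, n_species)
    for name, w in weights_beta.items():
        beta_true = beta_true + w * zs[name]
    log_scale = np.log2(scale_center_km) + rng.normal(0.0, noise_sd, n_species)
    for name, w in weights_scale.items():
        log_scale = log_scale + w * zs[name]
    log_radii = np.log2(np.asarray(radii_km, dtype=float))
    snapped = np.asarray(radii_km, dtype=float)[
        np.argmin(np.abs(log_scale[:, None] - log_radii[None, :]), axis=1)
    ]

    table = pd.DataFrame(values, index=pd.Index(labels, name="species_id"))
    for spec in specs:
        if spec.missing_rate > 0:
            miss = rng.random(n_species) < spec.missing_rate
            table.loc[miss, spec.name] = np.nan

    truths = [
        TruthRecord(
            species_id=labels[i],
            beta_true=float(beta_true[i]),
            scale_true_km=float(snapped[i]),
            alpha=0.0,
            trait_weights_beta=dict(weights_beta),
            trait_weights_scale=dict(weights_scale),
        )
        for i in range(n_species)
    ]
    return table, tree, truths
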