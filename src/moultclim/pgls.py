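"""Cross-species regression by phylogenetic generalized least squares (PGLS).

Residuals across species are not independent: under Brownian-motion trait
evolution their covariance equals the shared root-to-tip branch length on the
phylogeny.  Pagel's λ scales the off-diagonal (shared-history) entries of
that matrix between 0 (phylogenetic independence) and 1 (full Brownian
structure) and is estimated here by maximising the profile log-likelihood,
initialised from a 21-point grid and refined by bounded scalar optimisation;
ties break toward smaller λ because the profile can be flat at small n.

The F statistic, r² and residual variance follow the OLS analogues under the
GLS inner product (r² against a GLS intercept-only fit, residual variance on
n − p degrees of freedom); the reported log-likelihood is the ML variant used
for λ profiling.  p-values are two-tailed (for a single predictor the F test
equals the two-tailed t test on the slope).
"""

from __future__ import annotations

import dataclasses
import io
import logging
from collections.abc import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger("moultclim.pgls")

LAMBDA_GRID = np.linspace(0.0, 1.0, 21)
_TIE_TOL = 1e-9


class PglsError(ValueError):
    """Raised for malformed trees or invalid regression inputs."""


# ---------------------------------------------------------------------------
# Trees and covariance
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick tree, requiring unique tip labels and branch lengths on
    every non-root edge."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise PglsError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]
    if len(labels) != len(set(labels)):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise PglsError(f"duplicate tip labels: {dup}")
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise PglsError("unlabelled tip in tree")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise PglsError("tree has an edge with no branch length")
        if node.edge.length < 0:
            raise PglsError("negative branch length")
    return tree


def read_tree(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree))


def tree_to_newick(tree: dendropy.Tree) -> str:
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def brownian_vcv(tree: dendropy.Tree, tip_order: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance matrix: entry (i, j) is the shared
    root-to-tip path length of tips i and j; the diagonal holds tip depths."""
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [t for t in tip_order if t not in leaves]
    if missing:
        raise PglsError(f"species not found among tree tips: {missing}")
    depths = {}
    for label in tip_order:
        node = leaves[label]
        d = 0.0
        while node is not tree.seed_node:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[label] = d
    pdm = tree.phylogenetic_distance_matrix()
    n = len(tip_order)
    C = np.zeros((n, n))
    for i, a in enumerate(tip_order):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = tip_order[j]
            dist = pdm.distance(leaves[a].taxon, leaves[b].taxon)
            C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - dist)
    return C


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-8) -> bool:
    C = brownian_vcv(tree, tip_labels(tree))
    d = np.diag(C)
    return bool(np.max(d) - np.min(d) <= tol * max(np.max(d), 1.0))


def apply_lambda(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal entries of C by λ ∈ [0, 1]; diagonal unchanged."""
    if not (0.0 <= lam <= 1.0):
        raise PglsError(f"lambda must lie in [0, 1], got {lam}")
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


# ---------------------------------------------------------------------------
# GLS machinery
# ---------------------------------------------------------------------------

def _gls_solve(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Return (beta, rss, logdetV) for the GLS fit under covariance V."""
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise PglsError(f"singular covariance matrix: {exc}") from exc
    Vy = linalg.cho_solve(cf, y)
    VX = linalg.cho_solve(cf, X)
    XtVX = X.T @ VX
    try:
        beta = np.linalg.solve(XtVX, X.T @ Vy)
    except np.linalg.LinAlgError as exc:
        raise PglsError(f"singular GLS normal equations: {exc}") from exc
    r = y - X @ beta
    rss = float(r @ linalg.cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return beta, rss, logdet


def _profile_loglik(lam: float, y: np.ndarray, X: np.ndarray, C: np.ndarray) -> float:
    n = len(y)
    V = apply_lambda(C, lam)
    _, rss, logdet = _gls_solve(y, X, V)
    sigma2 = rss / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def _maximize_lambda(y: np.ndarray, X: np.ndarray, C: np.ndarray) -> float:
    grid_ll = np.array([_profile_loglik(l, y, X, C) for l in LAMBDA_GRID])
    best = int(np.argmax(grid_ll))
    lo = LAMBDA_GRID[max(best - 1, 0)]
    hi = LAMBDA_GRID[min(best + 1, len(LAMBDA_GRID) - 1)]
    candidates = [(grid_ll[best], float(LAMBDA_GRID[best]))]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda l: -_profile_loglik(l, y, X, C),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        candidates.append((-res.fun, float(res.x)))
    candidates.append((grid_ll[0], 0.0))
    candidates.append((grid_ll[-1], 1.0))
    best_ll = max(ll for ll, _ in candidates)
    # ties (within tolerance) break toward smaller lambda
    return min(lam for ll, lam in candidates if ll >= best_ll - _TIE_TOL)


@dataclasses.dataclass
class PglsFit:
    """A PGLS regression fit under V(λ̂)."""

    lambda_hat: float
    lambda_mode: str  # "ML" or "fixed"
    coefficients: dict[str, float]
    residual_variance: float
    r_squared: float | None
    f_statistic: float | None
    df: tuple[int, int]
    p_value: float | None
    log_likelihood: float
    n: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["df"] = list(self.df)
        return d


def pgls_fit(
    response: pd.Series,
    predictors: pd.DataFrame | None,
    tree: dendropy.Tree,
    lambda_mode: str | float = "ML",
) -> PglsFit:
    """PGLS of ``response`` on ``predictors`` (both indexed by species_id).

    ``lambda_mode`` is "ML" (maximum-likelihood λ over [0, 1]) or a fixed
    value in [0, 1].  ``predictors=None`` fits the intercept-only model (used
    for phylogenetic-signal estimation); r²/F/p are then undefined.
    """
    species = list(response.index)
    if len(species) != len(set(species)):
        raise PglsError("duplicate species in response")
    y = response.to_numpy(dtype=float)
    if predictors is not None:
        predictors = predictors.loc[species]
        for col in predictors.columns:
            if np.ptp(predictors[col].to_numpy(dtype=float)) == 0.0:
                raise PglsError(f"predictor {col!r} is constant across species")
        X = np.column_stack(
            [np.ones(len(species))] + [predictors[c].to_numpy(dtype=float) for c in predictors]
        )
        names = ["intercept"] + list(predictors.columns)
    else:
        X = np.ones((len(species), 1))
        names = ["intercept"]
    n, p = X.shape
    if p > 1 and n < p + 1:
        raise PglsError(f"need at least {p + 1} species for {p - 1} predictor(s), got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise PglsError("design matrix is rank deficient")
    if not is_ultrametric(tree):
        logger.warning("tree is not ultrametric; Pagel's lambda interpretation weakens")
    C = brownian_vcv(tree, species)

    if isinstance(lambda_mode, str):
        if lambda_mode != "ML":
            raise PglsError("lambda_mode must be 'ML' or a value in [0, 1]")
        lam = _maximize_lambda(y, X, C)
        mode = "ML"
    else:
        lam = float(lambda_mode)
        if not (0.0 <= lam <= 1.0):
            raise PglsError(f"lambda must lie in [0, 1], got {lam}")
        mode = "fixed"

    V = apply_lambda(C, lam)
    beta, rss, _ = _gls_solve(y, X, V)
    df1, df2 = p - 1, n - p
    resid_var = rss / df2 if df2 > 0 else np.nan
    if df1 > 0:
        _, tss, _ = _gls_solve(y, np.ones((n, 1)), V)
        r2 = 1.0 - rss / tss
        r2 = float(min(max(r2, 0.0), 1.0))
        f_stat = (r2 / df1) / ((1.0 - r2) / df2) if r2 < 1.0 else np.inf
        p_value = float(stats.f.sf(f_stat, df1, df2))
    else:
        r2, f_stat, p_value = None, None, None
    return PglsFit(
        lambda_hat=float(lam),
        lambda_mode=mode,
        coefficients=dict(zip(names, (float(b) for b in beta))),
        residual_variance=float(resid_var),
        r_squared=r2,
        f_statistic=None if f_stat is None else float(f_stat),
        df=(df1, df2),
        p_value=p_value,
        log_likelihood=float(_profile_loglik(lam, y, X, C)),
        n=n,
    )


# ---------------------------------------------------------------------------
# Comparative analyses
# ---------------------------------------------------------------------------

def group_contrast(
    trait: pd.Series,
    groups: pd.Series,
    tree: dendropy.Tree,
    lambda_mode: str | float = "ML",
) -> PglsFit:
    """PGLS of a species trait on a two-level group indicator (e.g. short- vs
    long-distance migration, pre- vs post-migration moult)."""
    groups = groups.loc[trait.index]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise PglsError(f"group contrast needs exactly two groups, got {levels}")
    counts = groups.value_counts()
    if counts.min() < 2:
        raise PglsError("each group needs at least two species")
    indicator = (groups == levels[1]).astype(float)
    predictors = pd.DataFrame({f"group[{levels[1]}]": indicator})
    return pgls_fit(trait, predictors, tree, lambda_mode=lambda_mode)


def ornamentation_regression(
    interaction_coefficients: pd.Series,
    ornament_male: pd.Series,
    ornament_female: pd.Series,
    tree: dendropy.Tree,
    lambda_mode: str | float = "ML",
) -> PglsFit:
    """PGLS of the per-species GMTA×sex interaction coefficient (male relative
    to female) on the male − female plumage ornamentation difference."""
    species = list(interaction_coefficients.index)
    for name, s in (("ornament_male", ornament_male), ("ornament_female", ornament_female)):
        missing = [sp for sp in species if sp not in s.index or pd.isna(s.loc[sp])]
        if missing:
            raise PglsError(f"missing {name} score for species: {missing}")
    diff = ornament_male.loc[species].astype(float) - ornament_female.loc[species].astype(float)
    predictors = pd.DataFrame({"ornament_diff": diff.to_numpy()}, index=species)
    return pgls_fit(interaction_coefficients, predictors, tree, lambda_mode=lambda_mode)
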