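"""Per-species Gamma GLMs with identity link, selected by AICc.

Moult extent (moulted area in mm², or relative extent) is strictly positive
and right-skewed, so each species is modelled with a Gamma GLM whose mean
equals the linear predictor directly (identity link g(µ) = µ):

    y_i ~ Gamma(shape ν, mean µ_i),   µ_i = x_iᵀβ

Candidate mean structures are hierarchical subsets of {GMTA, sex, GMTA×sex}
(sex terms only in sexually dichromatic species), compared by AICc with the
shape parameter counted in k.  A candidate is *selected* only when the
runner-up's ΔAICc strictly exceeds a threshold (default 2.00); otherwise
selection is ambiguous ("none").

Estimation: IRLS for β (for the identity link the working response is y
itself and the weights are 1/µ²), with step-halving whenever an update would
drive any fitted mean non-positive; β̂ does not depend on ν for a Gamma GLM,
so ν is then profiled out by maximum likelihood (Newton-free: solve
log ν − ψ(ν) = mean(y/µ̂ − 1 + log µ̂ − log y) by bracketing).
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .gmta import GmtaSeries
from .scoring import (
    FeatherTractLayout,
    MoultRecord,
    TractAreaTable,
    score_records,
)

logger = logging.getLogger("moultclim.glm")

GAMMA_SUPPORT_MSG = "Gamma responses must be strictly positive"

MAX_ITER = 200
REL_TOL = 1e-10


class GlmError(ValueError):
    """Raised for invalid designs/responses or failed convergence."""


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

TERMS = ("gmta", "sex", "gmta:sex")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A candidate mean structure: intercept plus a subset of the terms
    {gmta, sex, gmta:sex}; the interaction requires both main effects."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(t not in TERMS for t in self.terms):
            raise GlmError(f"unknown terms in {self.terms}")
        if len(set(self.terms)) != len(self.terms):
            raise GlmError("duplicate terms")
        if "gmta:sex" in self.terms and not {"gmta", "sex"}.issubset(self.terms):
            raise GlmError("interaction requires both gmta and sex main effects")

    @property
    def label(self) -> str:
        return "intercept" if not self.terms else "+".join(self.terms)

    @property
    def has_interaction(self) -> bool:
        return "gmta:sex" in self.terms

    def design(self, data: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
        """Design matrix from a frame with columns gmta and sex01 (female=0,
        male=1)."""
        cols = [np.ones(len(data))]
        names = ["intercept"]
        for term in self.terms:
            if term == "gmta":
                cols.append(data["gmta"].to_numpy(dtype=float))
            elif term == "sex":
                cols.append(data["sex01"].to_numpy(dtype=float))
            else:
                cols.append(
                    data["gmta"].to_numpy(dtype=float) * data["sex01"].to_numpy(dtype=float)
                )
            names.append(term)
        return np.column_stack(cols), tuple(names)


def build_candidate_set(dichromatic: bool) -> list[ModelSpec]:
    """Hierarchical candidates: monomorphic species can only test GMTA;
    dichromatic species add sex and the GMTA×sex interaction."""
    candidates = [ModelSpec(()), ModelSpec(("gmta",))]
    if dichromatic:
        candidates += [
            ModelSpec(("sex",)),
            ModelSpec(("gmta", "sex")),
            ModelSpec(("gmta", "sex", "gmta:sex")),
        ]
    return candidates


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelFit:
    """A fitted Gamma identity-link GLM with its AICc."""

    spec: ModelSpec
    coefficients: dict[str, float]
    shape: float
    log_likelihood: float
    n: int
    k: int  # mean parameters + 1 for the shape
    aicc: float
    fitted: np.ndarray = dataclasses.field(repr=False, default=None)


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); requires n > k + 1."""
    if n <= k + 1:
        raise GlmError(f"AICc undefined for n={n}, k={k} (needs n > k + 1)")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, shape: float) -> float:
    return float(np.sum(stats.gamma.logpdf(y, a=shape, scale=mu / shape)))


def _profile_shape(y: np.ndarray, mu: np.ndarray) -> float:
    """ML estimate of the Gamma shape ν given fitted means."""
    c = float(np.mean(np.log(mu) - np.log(y) + y / mu - 1.0))
    c = max(c, 1e-12)  # exact fit: shape is effectively infinite

    def h(log_nu: float) -> float:
        nu = np.exp(log_nu)
        return np.log(nu) - special.digamma(nu) - c

    # log ν − ψ(ν) decreases from +inf (ν→0) to 0 (ν→inf)
    return float(np.exp(optimize.brentq(h, -30.0, 30.0, xtol=1e-12)))


def fit_gamma_identity(
    y: Sequence[float] | np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    spec: ModelSpec | None = None,
) -> ModelFit:
    """Fit a Gamma GLM with identity link by IRLS with positivity-preserving
    step-halving, then profile-ML for the shape.

    ``X`` must contain an intercept column and be full column rank; all
    responses must be strictly positive.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise GlmError("response and design dimensions do not match")
    if np.any(y <= 0.0):
        i = int(np.argmax(y <= 0.0))
        raise GlmError(f"{GAMMA_SUPPORT_MSG}; observation {i} has y={y[i]}")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise GlmError("design matrix is rank deficient")
    if n <= p + 1:
        raise GlmError(f"need n > {p + 1} observations for {p} mean parameters, got {n}")
    names = tuple(names) if names is not None else tuple(f"b{j}" for j in range(p))

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu = X @ beta
    if np.any(mu <= 0.0):
        # fall back to a flat start at the sample mean
        beta = np.zeros(p)
        intercept_col = int(np.argmax(np.all(X == 1.0, axis=0)))
        beta[intercept_col] = float(np.mean(y))
        mu = X @ beta
    deviance = _gamma_deviance(y, mu)
    for _ in range(MAX_ITER):
        w = 1.0 / mu**2
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ y)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
            raise GlmError(f"IRLS normal equations singular: {exc}") from exc
        halvings = 0
        while np.any(X @ beta_new <= 0.0):
            beta_new = 0.5 * (beta + beta_new)
            halvings += 1
            if halvings > 60:
                raise GlmError("no IRLS step keeps all fitted means positive")
        beta = beta_new
        mu = X @ beta
        deviance_new = _gamma_deviance(y, mu)
        if abs(deviance_new - deviance) < REL_TOL * (abs(deviance_new) + REL_TOL):
            deviance = deviance_new
            break
        deviance = deviance_new
    else:
        raise GlmError(f"IRLS did not converge in {MAX_ITER} iterations")

    shape = _profile_shape(y, mu)
    ll = _gamma_loglik(y, mu, shape)
    k = p + 1
    # AICc is undefined at n = k + 1; such a fit is still usable on its own
    aicc_value = aicc(ll, k, n) if n > k + 1 else float("nan")
    return ModelFit(
        spec=spec if spec is not None else ModelSpec(()),
        coefficients=dict(zip(names, (float(b) for b in beta))),
        shape=shape,
        log_likelihood=ll,
        n=n,
        k=k,
        aicc=aicc_value,
        fitted=mu,
    )


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SelectionResult:
    """AICc comparison of candidate fits; a model is selected only when the
    runner-up's ΔAICc strictly exceeds the threshold."""

    fits: list[ModelFit]
    delta_aicc: list[float]
    selected: ModelSpec | None
    threshold: float

    @property
    def best_fit(self) -> ModelFit:
        return self.fits[int(np.argmin([f.aicc for f in self.fits]))]

    def fit_for(self, label: str) -> ModelFit:
        for f in self.fits:
            if f.spec.label == label:
                return f
        raise GlmError(f"no candidate labelled {label!r}")

    @property
    def selected_fit(self) -> ModelFit | None:
        return None if self.selected is None else self.fit_for(self.selected.label)


def select_model(fits: Sequence[ModelFit], threshold: float = 2.0) -> SelectionResult:
    """Rank candidate fits by AICc; require all fits to share the same n."""
    if len(fits) < 2:
        raise GlmError("model selection needs at least two candidates")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise GlmError(f"candidates fit on differing numbers of observations: {sorted(ns)}")
    aiccs = np.array([f.aicc for f in fits])
    if np.any(np.isnan(aiccs)):
        raise GlmError("a candidate has undefined AICc (n too small); cannot select")
    best = int(np.argmin(aiccs))
    delta = aiccs - aiccs[best]
    runner_up = float(np.min(np.delete(delta, best)))
    selected = fits[best].spec if runner_up > threshold else None
    return SelectionResult(
        fits=list(fits), delta_aicc=[float(d) for d in delta], selected=selected,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Per-species analysis
# ---------------------------------------------------------------------------

K_MAX_DICHROMATIC = 5  # intercept + gmta + sex + interaction + shape
K_MAX_MONOMORPHIC = 3

MIN_KNOWN_SEX_FRACTION = 0.9


def per_species_analysis(
    records: Iterable[MoultRecord],
    areas: TractAreaTable,
    layout: FeatherTractLayout,
    gmta: GmtaSeries,
    metadata: pd.DataFrame,
    response: str = "area",
    covariate: str = "gmta",
    threshold: float = 2.0,
    on_zero: str = "drop",
) -> dict[str, SelectionResult]:
    """Fit and select candidate models for every species.

    ``metadata`` is indexed by species_id with at least a boolean
    ``dichromatic`` column.  The response is the moulted area (mm²) or the
    relative extent; the covariate is the collection year's anomaly, or the
    (mean-centred) year itself when ``covariate='year'``.  Sex is coded
    female = 0, male = 1.  Zero-extent records are dropped with a logged
    count (``on_zero='drop'``) or raise (``on_zero='error'``) since the Gamma
    support is strictly positive.
    """
    if response not in ("area", "relative_extent"):
        raise GlmError("response must be 'area' or 'relative_extent'")
    if covariate not in ("gmta", "year"):
        raise GlmError("covariate must be 'gmta' or 'year'")
    if on_zero not in ("drop", "error"):
        raise GlmError("on_zero must be 'drop' or 'error'")
    table = score_records(records, areas, layout)
    table["response"] = table["area_mm2"] if response == "area" else table["relative_extent"]
    table["anomaly"] = [gmta.anomaly_for_year(y) for y in table["year"]]

    results: dict[str, SelectionResult] = {}
    for species, sub in table.groupby("species_id", sort=True):
        if species not in metadata.index:
            raise GlmError(f"species {species!r} missing from metadata")
        dichromatic = bool(metadata.loc[species, "dichromatic"])
        zero = sub["response"] <= 0.0
        if zero.any():
            if on_zero == "error":
                row = sub.loc[zero.idxmax()]
                raise GlmError(
                    f"{GAMMA_SUPPORT_MSG}: specimen {row['specimen_id']} of "
                    f"{species} has zero moult extent"
                )
            logger.info("%s: dropping %d zero-extent records", species, int(zero.sum()))
            sub = sub[~zero]
        if dichromatic:
            known = sub["sex"].isin(["male", "female"])
            if known.mean() < MIN_KNOWN_SEX_FRACTION:
                logger.warning(
                    "%s: only %.0f%% of records have known sex; species excluded",
                    species, 100 * known.mean(),
                )
                continue
            n_dropped = int((~known).sum())
            if n_dropped:
                logger.info("%s: dropping %d unknown-sex records", species, n_dropped)
            sub = sub[known]
        data = pd.DataFrame(
            {
                "response": sub["response"].to_numpy(dtype=float),
                "gmta": (
                    sub["anomaly"].to_numpy(dtype=float)
                    if covariate == "gmta"
                    else sub["year"].to_numpy(dtype=float) - sub["year"].mean()
                ),
                "sex01": (sub["sex"] == "male").to_numpy(dtype=float),
            }
        )
        k_max = K_MAX_DICHROMATIC if dichromatic else K_MAX_MONOMORPHIC
        if len(data) <= k_max + 1:
            logger.warning("%s: n=%d too small for the candidate set; skipped", species, len(data))
            continue
        fits = []
        for spec in build_candidate_set(dichromatic):
            X, names = spec.design(data)
            fits.append(fit_gamma_identity(data["response"], X, names, spec=spec))
        results[species] = select_model(fits, threshold=threshold)
    return results


def selection_table(results: dict[str, SelectionResult]) -> pd.DataFrame:
    """Flatten per-species selection results into one row per candidate."""
    rows = []
    for species in sorted(results):
        res = results[species]
        for fit, delta in zip(res.fits, res.delta_aicc):
            rows.append(
                {
                    "species_id": species,
                    "candidate": fit.spec.label,
                    "k": fit.k,
                    "n": fit.n,
                    "log_lik": fit.log_likelihood,
                    "aicc": fit.aicc,
                    "delta_aicc": delta,
                    "selected": res.selected is not None and fit.spec == res.selected,
                    "coefficients": ";".join(
                        f"{name}={value:.10g}" for name, value in fit.coefficients.items()
                    ),
                    "shape": fit.shape,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "candidate", "k", "n", "log_lik", "aicc",
            "delta_aicc", "selected", "coefficients", "shape",
        ],
    )
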