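"""Statistical linkage of network position to pollination function.

Quasi-likelihood GLMs (quasi-Poisson for counts, quasi-binomial for
fertilized-pod proportions, gaussian for node metrics) fitted by IRLS with
prior weights; dispersion is estimated as Pearson chi-square over residual
degrees of freedom and inference uses t statistics on the residual df.
Site-level models are weighted with the per-site variance of the response
(the study convention for averaged responses; an ``inverse_variance`` scheme
is available since inverse weighting is the usual statistical choice).

Also: land-use factor comparisons with dispersion-scaled F tests, pairwise
distance-versus-metric-similarity regressions (haversine distances; the
pairs are non-independent and a note records that this mirrors the simple
linear-model approach), and AICc-based single-predictor model selection
with the intercept-only guard (if the intercept-only model ranks first, no
candidate is considered suitable).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io import SiteReproduction, ValidationError

logger = logging.getLogger("polliscape")

__all__ = [
    "GlmFit",
    "ModelSelectionTable",
    "fit_quasi_glm",
    "reproduction_models",
    "landuse_comparisons",
    "distance_similarity",
    "aicc_selection",
    "haversine_km",
]

FAMILIES = ("quasipoisson_log", "quasibinomial_logit", "gaussian_identity")

EARTH_RADIUS_KM = 6371.0088


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""


@dataclass
class GlmFit:
    """A fitted (quasi-)GLM: point estimates, dispersion-scaled inference."""

    family: str
    response: str
    coefficients: dict[str, float]
    se: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    dispersion: float
    n: int
    df_resid: int
    weights_used: str
    deviance: float = float("nan")
    null_deviance: float = float("nan")
    f_stat: float = float("nan")
    f_p: float = float("nan")
    notes: tuple[str, ...] = ()

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)

    def slope(self, term: str) -> float:
        return self.coefficients[term]


def _family_obj(family: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        if family == "quasipoisson_log":
            return sm.families.Poisson()
        if family == "quasibinomial_logit":
            return sm.families.Binomial()
        if family == "gaussian_identity":
            return sm.families.Gaussian()
    raise ValidationError(f"unknown family {family!r}; expected one of {FAMILIES}")


def fit_quasi_glm(
    y,
    X: pd.DataFrame,
    family: str,
    weights=None,
    response_name: str = "y",
    weights_used: str = "unit",
) -> GlmFit:
    """Fit a quasi-likelihood GLM with optional prior (variance) weights.

    ``X`` must already contain an intercept column if one is wanted.  Point
    estimates solve the same score equations as the ordinary likelihood fit;
    the dispersion (Pearson chi-square / residual df) only scales the
    standard errors.  p-values use the t distribution on the residual df.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValidationError("response and design matrix lengths differ")
    if n <= X.shape[1]:
        raise ValidationError(f"need n > n_params ({n} observations, {X.shape[1]} parameters)")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or not (w > 0).any():
            raise ValidationError("weights must be nonnegative and not all zero")
        if (w == 0).any():
            logger.warning("%d zero-weight observation(s) contribute nothing to the fit",
                           int((w == 0).sum()))
            w = np.where(w == 0, 1e-12, w)  # keep the IRLS well defined
    else:
        w = None

    if np.ptp(y) == 0.0:
        # constant response: perfect intercept fit; statsmodels' IRLS cannot
        # form a scale here, so report the degenerate fit directly
        return _constant_fit(y, X, family, response_name, weights_used)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer binomial/poisson endog is intended here
        model = sm.GLM(y, X, family=_family_obj(family), var_weights=w)
        res = model.fit(maxiter=100, tol=1e-9, scale="X2")
    if not getattr(res, "converged", True):
        raise ConvergenceError(
            f"IRLS did not converge in 100 iterations; deviance trace: "
            f"{getattr(res, 'fit_history', {}).get('deviance', [])}"
        )

    names = list(X.columns)
    coefs = dict(zip(names, np.asarray(res.params, dtype=float)))
    ses = dict(zip(names, np.asarray(res.bse, dtype=float)))
    df_resid = int(res.df_resid)
    tvals = {k: (coefs[k] / ses[k] if ses[k] > 0 else float("nan")) for k in names}
    pvals = {
        k: float(2.0 * scipy.stats.t.sf(abs(tvals[k]), df_resid)) if np.isfinite(tvals[k]) else float("nan")
        for k in names
    }
    notes: list[str] = []
    if family == "quasibinomial_logit" and max(abs(v) for v in coefs.values()) > 15:
        notes.append("possible separation: unbounded coefficient(s)")
        logger.warning("quasi-binomial fit for %s shows signs of separation", response_name)
    return GlmFit(
        family=family,
        response=response_name,
        coefficients=coefs,
        se=ses,
        t_values=tvals,
        p_values=pvals,
        dispersion=float(res.scale),
        n=n,
        df_resid=df_resid,
        weights_used=weights_used,
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        notes=tuple(notes),
    )


def _constant_fit(
    y: np.ndarray, X: pd.DataFrame, family: str, response_name: str, weights_used: str
) -> GlmFit:
    y0 = float(y[0])
    if family == "quasipoisson_log":
        intercept = np.log(y0) if y0 > 0 else -np.inf
    elif family == "quasibinomial_logit":
        intercept = np.log(y0 / (1 - y0)) if 0 < y0 < 1 else np.copysign(np.inf, y0 - 0.5)
    else:
        intercept = y0
    names = list(X.columns)
    coefs = {k: (intercept if k == names[0] else 0.0) for k in names}
    zeros = {k: 0.0 for k in names}
    nans = {k: float("nan") for k in names}
    return GlmFit(
        family=family,
        response=response_name,
        coefficients=coefs,
        se=zeros,
        t_values=nans,
        p_values=nans,
        dispersion=0.0,
        n=len(y),
        df_resid=len(y) - len(names),
        weights_used=weights_used,
        deviance=0.0,
        null_deviance=0.0,
        notes=("degenerate fit: constant response",),
    )


def _design(x: np.ndarray, name: str) -> pd.DataFrame:
    return pd.DataFrame({"intercept": np.ones(len(x)), name: np.asarray(x, dtype=float)})


def _pick_weights(var: np.ndarray, scheme: str) -> tuple[np.ndarray, str]:
    var = np.asarray(var, dtype=float)
    if scheme == "variance":
        return var, "variance"
    if scheme == "inverse_variance":
        safe = np.where(var > 0, var, np.nan)
        if np.isnan(safe).any():
            logger.warning("zero response variance at %d site(s); replaced by smallest positive",
                           int(np.isnan(safe).sum()))
            safe = np.where(np.isnan(safe), np.nanmin(safe), safe)
        return 1.0 / safe, "inverse_variance"
    raise ValidationError(f"unknown weight scheme {scheme!r}")


def reproduction_models(
    site_metrics: pd.DataFrame,
    repro: list[SiteReproduction] | pd.DataFrame,
    weight_scheme: str = "variance",
) -> dict[str, GlmFit]:
    """The four site-level reproduction-versus-network-position models.

    fertilized-pod proportion ~ c and ~ d' (quasi-binomial) and mean seeds
    per pod ~ c and ~ d' (quasi-Poisson), each weighted by the per-site
    response variance under ``weight_scheme``.  ``site_metrics`` needs
    columns site_id, c, d_prime.
    """
    if isinstance(repro, list):
        repro = pd.DataFrame([vars(r) for r in repro])
    merged = site_metrics.merge(repro, on="site_id", how="inner")
    if len(merged) < 5:
        raise ValidationError(f"only {len(merged)} matched sites; need at least 5")

    fits: dict[str, GlmFit] = {}
    w_fert, scheme_name = _pick_weights(merged["var_fert_prop"].to_numpy(), weight_scheme)
    w_seed, _ = _pick_weights(merged["var_seeds"].to_numpy(), weight_scheme)
    for metric in ("c", "d_prime"):
        x = merged[metric].to_numpy(dtype=float)
        fits[f"fert_prop~{metric}"] = fit_quasi_glm(
            merged["mean_fert_prop"].to_numpy(),
            _design(x, metric),
            "quasibinomial_logit",
            weights=w_fert,
            response_name="mean_fert_prop",
            weights_used=scheme_name,
        )
        fits[f"seeds~{metric}"] = fit_quasi_glm(
            merged["mean_seeds"].to_numpy(),
            _design(x, metric),
            "quasipoisson_log",
            weights=w_seed,
            response_name="mean_seeds",
            weights_used=scheme_name,
        )
    for name, fit in fits.items():
        term = name.split("~")[1]
        direction = "increases" if fit.coefficients[term] > 0 else "decreases"
        logger.info("%s: reproduction %s with %s (slope %.4g, p %.3g)",
                    name, direction, term, fit.coefficients[term], fit.p_values[term])
    return fits


def landuse_comparisons(
    site_table: pd.DataFrame,
    responses: dict[str, str],
    weights: dict[str, np.ndarray] | None = None,
    group_col: str = "land_use",
) -> dict[str, GlmFit]:
    """Per-response GLMs with a land-use factor and an overall F test.

    ``responses`` maps response column -> family.  The F statistic compares
    the factor model against intercept-only by the dispersion-scaled
    deviance difference on (groups - 1, residual df).
    """
    groups = site_table[group_col].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValidationError("need at least two land uses to compare")
    # treatment coding against the first level (alphabetical)
    X = pd.DataFrame({"intercept": np.ones(len(site_table))})
    for lv in levels[1:]:
        X[f"{group_col}[{lv}]"] = (groups == lv).astype(float).to_numpy()
    X0 = X[["intercept"]]

    out: dict[str, GlmFit] = {}
    for col, family in responses.items():
        y = site_table[col].to_numpy(dtype=float)
        w = None if weights is None else weights.get(col)
        wname = "unit" if w is None else "variance"
        fit = fit_quasi_glm(y, X, family, weights=w, response_name=col, weights_used=wname)
        fit0 = fit_quasi_glm(y, X0, family, weights=w, response_name=col, weights_used=wname)
        df_num = len(levels) - 1
        if fit.dispersion > 0:
            f_stat = ((fit0.deviance - fit.deviance) / df_num) / fit.dispersion
            f_stat = max(f_stat, 0.0)
            f_p = float(scipy.stats.f.sf(f_stat, df_num, fit.df_resid))
        else:  # responses identical within machine precision
            f_stat, f_p = 0.0, 1.0
        fit.f_stat, fit.f_p = float(f_stat), f_p
        out[col] = fit
    return out


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres (Earth radius 6371.0088 km)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def distance_similarity(
    site_metrics: pd.DataFrame, metric_cols: tuple[str, ...] = ("c", "d_prime")
) -> dict[str, GlmFit]:
    """Pairwise |metric difference| regressed on pairwise distance (km).

    One ordinary linear regression per metric over all unordered site pairs.
    The absolute difference is a dissimilarity: a negative slope means sites
    further apart are MORE similar.  Pairs sharing sites are not independent;
    the fits carry a note saying so rather than correcting for it.
    """
    need = {"site_id", "latitude", "longitude", *metric_cols}
    missing_cols = need - set(site_metrics.columns)
    if missing_cols:
        raise ValidationError(f"site metrics missing column(s): {sorted(missing_cols)}")
    bad = site_metrics[site_metrics[["latitude", "longitude"]].isna().any(axis=1)]
    if len(bad):
        raise ValidationError(f"missing coordinates for site(s): {bad['site_id'].tolist()}")
    if len(site_metrics) < 3:
        raise ValidationError("need at least 3 sites for pairwise regressions")

    rows = site_metrics.reset_index(drop=True)
    dists, diffs = [], {m: [] for m in metric_cols}
    for a, b in itertools.combinations(range(len(rows)), 2):
        ra, rb = rows.iloc[a], rows.iloc[b]
        dists.append(haversine_km(ra.latitude, ra.longitude, rb.latitude, rb.longitude))
        for m in metric_cols:
            diffs[m].append(abs(float(ra[m]) - float(rb[m])))
    dists = np.asarray(dists)

    out = {}
    for m in metric_cols:
        fit = fit_quasi_glm(
            np.asarray(diffs[m]),
            _design(dists, "distance_km"),
            "gaussian_identity",
            response_name=f"|delta {m}|",
        )
        fit.notes = fit.notes + (
            "pairwise observations share sites and are not independent",
        )
        out[m] = fit
    return out


@dataclass
class ModelSelectionTable:
    """AICc ranking of intercept-only plus single-predictor gaussian models."""

    table: pd.DataFrame  # columns: model, k, aicc, delta_aicc, rank, most_explanatory
    best_is_intercept_only: bool

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])

    @property
    def suitable_models(self) -> list[str]:
        """Candidates within delta AICc < 2, unless the intercept guard fired."""
        if self.best_is_intercept_only:
            return []
        sel = self.table[self.table["most_explanatory"] & (self.table["model"] != "intercept_only")]
        return sel["model"].tolist()


def _gaussian_aicc(y: np.ndarray, X: pd.DataFrame) -> tuple[float, int]:
    n = len(y)
    k = X.shape[1] + 1  # + the variance parameter
    if n - k - 1 <= 0:
        raise ValidationError(f"AICc undefined: n - k - 1 = {n - k - 1} for k = {k}")
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    aic = -2.0 * res.llf + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1), k


def aicc_selection(y, predictors: dict[str, np.ndarray]) -> ModelSelectionTable:
    """Rank gaussian single-predictor models (plus intercept-only) by AICc.

    Models within delta AICc < 2 of the best are flagged most explanatory;
    if intercept-only ranks first no candidate is considered suitable.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    rows = []
    aicc0, k0 = _gaussian_aicc(y, pd.DataFrame({"intercept": np.ones(n)}))
    rows.append({"model": "intercept_only", "k": k0, "aicc": aicc0})
    for name, x in predictors.items():
        x = np.asarray(x, dtype=float)
        if len(x) != n:
            raise ValidationError(f"predictor {name!r} length {len(x)} != n {n}")
        aicc, k = _gaussian_aicc(y, _design(x, name))
        rows.append({"model": name, "k": k, "aicc": aicc})
    tab = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab["most_explanatory"] = tab["delta_aicc"] < 2.0
    best_io = tab.iloc[0]["model"] == "intercept_only"
    if best_io:
        logger.info("intercept-only model ranks first: no predictor considered suitable")
    return ModelSelectionTable(table=tab, best_is_intercept_only=bool(best_io))
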