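"""Generalized least squares with AR(1) errors over ordered time bins.

Metric series over consecutive land-mammal-age bins are temporally
autocorrelated, so climate/sampling drivers are inferred by GLS with a
first-order autoregressive error correlation (corAR1-style, indexed by bin
order). Estimation is maximum likelihood: for each candidate phi the model
is transformed by the AR(1) Cholesky factor (Prais-Winsten), beta and
sigma^2 are profiled out by OLS, and the profile likelihood is maximized
over phi in (-0.99, 0.99) by bounded 1-D optimization. ML (not REML) so
that AIC values are comparable across fixed-effect structures.

Model selection enumerates all predictor subsets respecting marginality
(a quadratic term requires its main effect, an interaction requires both),
fits each by AR(1)-GLS, and ranks by AIC (MuMIn-style dredge).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "GLSAR1",
    "fit_gls_ar1",
    "enumerate_models",
    "model_select",
    "variance_explained",
    "aggregate_to_bins",
]

PHI_BOUND = 0.99


def _ar1_transform(Z: np.ndarray, phi: float) -> np.ndarray:
    """Whitening transform for AR(1) correlation on equally spaced points."""
    out = np.empty_like(Z, dtype=float)
    out[0] = np.sqrt(1.0 - phi**2) * Z[0]
    out[1:] = Z[1:] - phi * Z[:-1]
    return out


class GLSAR1(BaseEstimator, RegressorMixin):
    """GLS regression with AR(1) errors, phi estimated by profile ML.

    Parameters
    ----------
    fit_intercept : include an intercept column (default True).
    phi : if not None, fix the autoregressive coefficient instead of
        estimating it (phi=0 reduces exactly to OLS).

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : GLS coefficient estimates.
    phi_ : AR(1) coefficient (estimated or fixed).
    sigma2_ : ML innovation variance.
    loglik_, aic_ : maximized log-likelihood and AIC (k counts the
        coefficients plus phi plus sigma^2).
    bse_, tvalues_, pvalues_ : coefficient standard errors, t and p values
        from the GLS covariance with n - p residual degrees of freedom.
    """

    def __init__(self, fit_intercept: bool = True, phi: float | None = None):
        self.fit_intercept = fit_intercept
        self.phi = phi

    # -- likelihood ---------------------------------------------------------
    @staticmethod
    def _profile(y: np.ndarray, X: np.ndarray, phi: float):
        yt = _ar1_transform(y, phi)
        Xt = _ar1_transform(X, phi)
        beta, _, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError("singular transformed design matrix")
        resid = yt - Xt @ beta
        n = len(y)
        rss = float(resid @ resid)
        sigma2 = max(rss / n, 1e-300)
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + 0.5 * np.log(1.0 - phi**2)
        return beta, sigma2, loglik, Xt

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if not np.isfinite(y).all() or not np.isfinite(X).all():
            raise ValueError("non-finite values in y or X")
        n = len(y)
        design = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        p = design.shape[1]
        if n < p + 2:
            raise ValueError(f"need at least {p + 2} observations for {p} coefficients")

        if self.phi is not None:
            phi_hat = float(self.phi)
        else:
            def neg_profile(phi):
                try:
                    return -self._profile(y, design, phi)[2]
                except np.linalg.LinAlgError:
                    return np.inf

            res = optimize.minimize_scalar(
                neg_profile, bounds=(-PHI_BOUND, PHI_BOUND), method="bounded",
                options={"xatol": 1e-6},
            )
            phi_hat = float(res.x)
        beta, sigma2, loglik, Xt = self._profile(y, design, phi_hat)

        # GLS covariance with the unbiased variance estimate for t tests
        XtX_inv = np.linalg.inv(Xt.T @ Xt)
        dof = max(n - p, 1)
        s2_unbiased = sigma2 * n / dof
        cov = XtX_inv * s2_unbiased

        self.n_, self.p_ = n, p
        self.phi_ = phi_hat
        self.sigma2_ = sigma2
        self.loglik_ = float(loglik)
        self.k_ = p + 2  # coefficients + phi + sigma^2
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.k_
        self.params_ = beta
        self.bse_ = np.sqrt(np.diag(cov))
        self.tvalues_ = beta / self.bse_
        self.pvalues_ = 2.0 * stats.t.sf(np.abs(self.tvalues_), dof)
        self.df_resid_ = dof
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    @property
    def fittedvalues_(self) -> np.ndarray:
        raise AttributeError("call predict on the design used for fitting")


@dataclass(frozen=True)
class GlsFit:
    """Summary of one AR(1)-GLS fit."""

    terms: tuple[str, ...]
    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    phi: float
    sigma2: float
    loglik: float
    k: int
    aic: float
    fitted: np.ndarray
    residuals: np.ndarray
    model: GLSAR1 = field(repr=False, compare=False, default=None)


def fit_gls_ar1(y, X: pd.DataFrame, phi: float | None = None) -> GlsFit:
    """Fit y on the columns of X (intercept added) with AR(1)-GLS.

    Rows must already be in temporal bin order.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = pd.DataFrame(X) if not isinstance(X, pd.DataFrame) else X
    est = GLSAR1(fit_intercept=True, phi=phi).fit(X.to_numpy(dtype=float), y)
    names = ["(Intercept)"] + list(X.columns)
    fitted = est.predict(X.to_numpy(dtype=float))
    return GlsFit(
        terms=tuple(X.columns),
        params=dict(zip(names, est.params_)),
        bse=dict(zip(names, est.bse_)),
        tvalues=dict(zip(names, est.tvalues_)),
        pvalues=dict(zip(names, est.pvalues_)),
        phi=est.phi_,
        sigma2=est.sigma2_,
        loglik=est.loglik_,
        k=est.k_,
        aic=est.aic_,
        fitted=fitted,
        residuals=y - fitted,
        model=est,
    )


# ---------------------------------------------------------------------------
# Model enumeration and selection

def _requirements(term: str) -> list[str]:
    """Marginality prerequisites implied by a term's name.

    'x^2' (or 'x2' via explicit rules) requires 'x'; 'a:b' requires both.
    """
    if ":" in term:
        return term.split(":")
    if term.endswith("^2"):
        return [term[:-2]]
    return []


def enumerate_models(terms: list[str], rules: dict[str, list[str]] | None = None) -> list[tuple[str, ...]]:
    """All predictor subsets respecting marginality, smallest first.

    ``rules`` maps a term to the terms it requires; defaults are derived
    from term names ('^2' suffix and ':' interactions). Includes the empty
    (intercept-only) model.
    """
    rules = dict(rules or {})
    for t in terms:
        rules.setdefault(t, _requirements(t))
    models: list[tuple[str, ...]] = []
    for k in range(len(terms) + 1):
        for combo in itertools.combinations(terms, k):
            chosen = set(combo)
            if all(set(rules.get(t, [])) <= chosen for t in combo):
                models.append(combo)
    return models


def variance_explained(fit: GlsFit | np.ndarray, y) -> float:
    """Variance explained by a model, in percent.

    Defined as the squared Pearson correlation between fitted and observed
    values, times 100 (0 for a constant fit).
    """
    fitted = fit.fitted if isinstance(fit, GlsFit) else np.asarray(fit, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    if np.ptp(fitted) == 0:
        return 0.0
    r = np.corrcoef(fitted, y)[0, 1]
    return float(r**2 * 100.0)


def _design_for(table: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    cols = {}
    for t in terms:
        if t in table.columns:
            cols[t] = table[t].to_numpy(dtype=float)
        elif ":" in t:
            a, b = t.split(":")
            cols[t] = table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float)
        elif t.endswith("^2"):
            cols[t] = table[t[:-2]].to_numpy(dtype=float) ** 2
        else:
            raise KeyError(f"term {t!r} not found in covariate table")
    return pd.DataFrame(cols, index=table.index)


@dataclass(frozen=True)
class ModelSelectionTable:
    """AIC ranking over candidate predictor sets."""

    table: pd.DataFrame                 # model, k, loglik, aic, delta_aic, var_explained, converged
    fits: dict[tuple[str, ...], GlsFit] = field(repr=False, compare=False, default=None)

    @property
    def best_terms(self) -> tuple[str, ...]:
        return tuple(self.table.iloc[0]["model"])

    @property
    def best_fit(self) -> GlsFit:
        return self.fits[self.best_terms]


def model_select(
    y,
    covariates: pd.DataFrame,
    terms: list[str] | None = None,
    rules: dict[str, list[str]] | None = None,
    *,
    standardize: bool = True,
) -> ModelSelectionTable:
    """Fit every marginality-respecting predictor subset; rank by AIC.

    ``terms`` may include derived terms ('map^2', 'area:n_taxa') that are
    built from the covariate columns. Covariates are z-scored before the
    derived terms are formed (AIC ranking is invariant to this, but it
    conditions the optimization). A model that fails to fit is recorded as
    unconverged, not fatal.
    """
    y = np.asarray(y, dtype=float).ravel()
    if terms is None:
        terms = list(covariates.columns)
    base = covariates.copy()
    if standardize:
        for c in base.columns:
            col = base[c].to_numpy(dtype=float)
            sd = col.std(ddof=0)
            base[c] = (col - col.mean()) / (sd if sd > 0 else 1.0)

    rows = []
    fits: dict[tuple[str, ...], GlsFit] = {}
    for combo in enumerate_models(terms, rules):
        try:
            X = _design_for(base, combo)
            fit = fit_gls_ar1(y, X)
            rows.append(
                {
                    "model": combo,
                    "k": fit.k,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "var_explained": variance_explained(fit, y),
                    "converged": True,
                }
            )
            fits[combo] = fit
        except (np.linalg.LinAlgError, ValueError) as err:
            rows.append(
                {"model": combo, "k": len(combo) + 3, "loglik": np.nan, "aic": np.nan,
                 "var_explained": np.nan, "converged": False}
            )
    tab = pd.DataFrame(rows)
    best = tab.loc[tab["converged"], "aic"].min()
    tab["delta_aic"] = tab["aic"] - best
    tab = tab.sort_values("aic", na_position="last").reset_index(drop=True)
    tab["best"] = tab["delta_aic"] == 0.0
    return ModelSelectionTable(table=tab, fits=fits)


# ---------------------------------------------------------------------------
# Covariate alignment

def aggregate_to_bins(
    ages, values, bins, how: str = "mean"
) -> np.ndarray:
    """Align a dated proxy series to time bins.

    ``bins`` is a sequence with ``older_ma``/``younger_ma`` attributes.
    'mean' averages source values whose ages fall inside each bin's range
    (falling back to nearest-age interpolation for empty bins); 'midpoint'
    linearly interpolates the series at the bin midpoint age.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(ages)
    ages, values = ages[order], values[order]
    out = np.empty(len(bins))
    for i, b in enumerate(bins):
        if how == "mean":
            inside = (ages <= b.older_ma) & (ages >= b.younger_ma)
            if inside.any():
                out[i] = values[inside].mean()
            else:
                out[i] = np.interp(b.midpoint_ma, ages, values)
        elif how == "midpoint":
            out[i] = np.interp(b.midpoint_ma, ages, values)
        else:
            raise ValueError(f"unknown aggregation {how!r}")
    return out
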