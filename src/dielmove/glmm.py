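"""Random-intercept mixed models for daily movement responses.

Two models share one fixed-effect structure — NDVI, social rank (reference
level "low"), their interaction, and the responses of the two previous days
as lagged covariates — plus a Gaussian random intercept per individual:

* diel displacement (DD, km): identity link, Gaussian residuals (a linear
  mixed model, fit by maximum likelihood);
* movement predictability (MP, proportion of 24 hours): logit link, with
  MP*24 treated as a binomial count of 24 trials; the lag covariates stay on
  the proportion scale.  Fit by adaptive Gauss-Hermite quadrature over the
  random intercept (Laplace mode + curvature re-centering), which keeps the
  likelihood exact enough for likelihood-ratio tests.

Both likelihoods are plain ML (no REML), so nested fixed-effect models can
be compared with likelihood-ratio chi-square tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_fprime, approx_hess

RANK_LEVELS = ("low", "medium", "variable", "high")
FULL_TERMS = ("ndvi", "rank", "ndvi:rank", "lag1", "lag2")
MP_TRIALS = 24


@dataclass(frozen=True)
class GlmmSpec:
    """Model specification: response, link, fixed terms, grouping."""

    response: str = "dd"  # 'dd' or 'mp'
    terms: tuple[str, ...] = FULL_TERMS
    grouping: str = "individual_id"

    @property
    def link(self) -> str:
        return {"dd": "identity", "mp": "logit"}[self.response]

    def __post_init__(self):
        if self.response not in ("dd", "mp"):
            raise ValueError("response must be 'dd' or 'mp'")
        unknown = set(self.terms) - set(FULL_TERMS)
        if unknown:
            raise ValueError(f"unknown terms: {sorted(unknown)}")
        if "ndvi:rank" in self.terms and not {"ndvi", "rank"} <= set(self.terms):
            raise ValueError("interaction requires both main effects")


@dataclass
class GlmmFit:
    """Fitted coefficients and likelihood for one mixed model."""

    spec: GlmmSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    re_var: float
    re_intercepts: pd.Series
    loglik: float
    n_rows: int
    converged: bool
    ndvi_range: tuple[float, float] | None = None
    rank_levels: tuple[str, ...] = RANK_LEVELS
    extra: dict = field(default_factory=dict)

    @property
    def param_names(self) -> list[str]:
        return list(self.params.index)


@dataclass
class LrtResult:
    """Likelihood-ratio test of nested fixed-effect structures."""

    chi2: float
    df: int
    p_value: float


def build_design(rows: pd.DataFrame, spec: GlmmSpec) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Design matrix (with intercept), response vector and group labels.

    Rank enters as dummies against the reference level "low"; the
    interaction multiplies each rank dummy by NDVI.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(rows))}
    present = [lv for lv in RANK_LEVELS if "rank" in rows.columns and (rows["rank"] == lv).any()]
    if "ndvi" in spec.terms:
        cols["ndvi"] = rows["ndvi"].to_numpy(dtype=float)
    if "rank" in spec.terms:
        for lv in present[1:]:
            cols[f"rank[{lv}]"] = (rows["rank"] == lv).to_numpy(dtype=float)
    if "ndvi:rank" in spec.terms:
        for lv in present[1:]:
            cols[f"ndvi:rank[{lv}]"] = cols["ndvi"] * (rows["rank"] == lv).to_numpy(dtype=float)
    for lag in ("lag1", "lag2"):
        if lag in spec.terms:
            cols[lag] = rows[lag].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=rows.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in np.flatnonzero(np.abs(np.diag(r)) < 1e-8)]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    y = rows["y"].to_numpy(dtype=float)
    groups = rows[spec.grouping].to_numpy()
    return X, y, groups


def _fit_lmm(X: pd.DataFrame, y: np.ndarray, groups: np.ndarray, spec: GlmmSpec) -> GlmmFit:
    model = sm.MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method=["lbfgs", "bfgs"])
            re_var = float(np.asarray(res.cov_re)[0, 0])
            degenerate = not np.isfinite(res.llf) or re_var < 1e-10
        except np.linalg.LinAlgError:
            degenerate = True
        if degenerate:
            # variance on the boundary: the ML solution is the ordinary
            # least-squares fit (MixedLM degenerates there)
            fit = _ols_fit(X, y, spec)
            fit.re_intercepts = pd.Series(0.0, index=pd.unique(groups))
            return fit
        params = pd.Series(np.asarray(res.fe_params), index=X.columns)
        bse = pd.Series(np.asarray(res.bse_fe), index=X.columns)
        try:
            re = pd.Series({g: float(v.iloc[0]) for g, v in res.random_effects.items()})
        except (ValueError, np.linalg.LinAlgError):
            # variance on the boundary: best predictors are all zero
            re = pd.Series(0.0, index=pd.unique(groups))
    return GlmmFit(
        spec=spec,
        params=params,
        bse=bse,
        tvalues=params / bse,
        re_var=re_var,
        re_intercepts=re,
        loglik=float(res.llf),
        n_rows=len(y),
        converged=bool(res.converged),
        extra={"residual_var": float(res.scale)},
    )


def _small_gradient(grad: np.ndarray, tol: float = 0.05) -> bool:
    return bool(np.max(np.abs(grad)) < tol)


class _BinomialAGQ:
    """Adaptive Gauss-Hermite likelihood for a binomial random-intercept GLMM."""

    def __init__(self, X, counts, trials, group_idx, n_groups, n_nodes=15):
        self.X = X
        self.counts = counts
        self.trials = trials
        self.gi = group_idx
        self.ng = n_groups
        self.z, self.w = np.polynomial.hermite.hermgauss(n_nodes)
        self.logw = np.log(self.w)
        self.const = float(
            np.sum(gammaln(trials + 1) - gammaln(counts + 1) - gammaln(trials - counts + 1))
        )
        self._b_warm = np.zeros(n_groups)

    def _segsum(self, v: np.ndarray) -> np.ndarray:
        return np.bincount(self.gi, weights=v, minlength=self.ng)

    def _cond_loglik_by_group(self, eta: np.ndarray) -> np.ndarray:
        ll = self.counts * eta - self.trials * np.logaddexp(0.0, eta)
        return self._segsum(ll)

    def loglik(self, beta: np.ndarray, sigma: float) -> float:
        eta0 = self.X @ beta
        if sigma < 1e-10:
            return float(self._cond_loglik_by_group(eta0).sum()) + self.const
        # Laplace mode of the per-group integrand
        b = self._b_warm.copy()
        inv_var = 1.0 / sigma**2
        for _ in range(100):
            p = expit(eta0 + b[self.gi])
            grad = self._segsum(self.counts - self.trials * p) - b * inv_var
            hess = -(self._segsum(self.trials * p * (1.0 - p)) + inv_var)
            step = grad / hess
            b -= step
            if np.max(np.abs(grad)) < 1e-9:
                break
        self._b_warm = b
        tau = 1.0 / np.sqrt(-hess)
        # adaptive nodes b_q = b_hat + sqrt(2) tau z_q
        bq = b[None, :] + np.sqrt(2.0) * tau[None, :] * self.z[:, None]
        h = np.empty((len(self.z), self.ng))
        for q in range(len(self.z)):
            h[q] = self._cond_loglik_by_group(eta0 + bq[q][self.gi])
        h -= 0.5 * bq**2 * inv_var
        log_int = special.logsumexp(
            h + self.z[:, None] ** 2 + self.logw[:, None], axis=0
        ) + np.log(np.sqrt(2.0) * tau)
        ll = log_int - 0.5 * np.log(2.0 * np.pi) - np.log(sigma)
        return float(ll.sum()) + self.const

    def posterior_modes(self, beta: np.ndarray, sigma: float) -> np.ndarray:
        self.loglik(beta, sigma)
        return self._b_warm.copy()


def _fit_binomial_glmm(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    spec: GlmmSpec,
    trials: int = MP_TRIALS,
    n_nodes: int = 15,
    force_zero_re: bool = False,
) -> GlmmFit:
    counts = np.rint(y * trials)
    if np.max(np.abs(counts - y * trials)) > 1e-6:
        raise ValueError(f"responses are not multiples of 1/{trials}")
    labels, gi = np.unique(groups, return_inverse=True)
    Xa = X.to_numpy()
    agq = _BinomialAGQ(Xa, counts, np.full(len(y), float(trials)), gi, len(labels), n_nodes)

    glm = sm.GLM(
        np.column_stack([counts, trials - counts]), Xa, family=sm.families.Binomial()
    ).fit()
    beta0 = np.asarray(glm.params)

    if force_zero_re:
        nll = lambda b: -agq.loglik(b, 0.0)
        jac = lambda b: approx_fprime(b, nll, centered=True)
        res = optimize.minimize(
            nll, beta0, jac=jac, method="BFGS", options={"gtol": 1e-6, "maxiter": 500}
        )
        beta_hat, sigma_hat = res.x, 0.0
        ll, ok = -res.fun, bool(res.success) or _small_gradient(jac(res.x))
    else:
        def nll(params):
            return -agq.loglik(params[:-1], abs(params[-1]))

        jac = lambda p: approx_fprime(p, nll, centered=True)
        x0 = np.append(beta0, 0.3)
        res = optimize.minimize(
            nll, x0, jac=jac, method="BFGS", options={"gtol": 1e-5, "maxiter": 500}
        )
        beta_hat, sigma_hat = res.x[:-1], abs(res.x[-1])
        # "precision loss" exits with a tiny gradient are converged in
        # practice; the curvature here is O(n), so |grad| ~ 0.05 bounds the
        # parameter error around 1e-5
        ll, ok = -res.fun, bool(res.success) or _small_gradient(jac(res.x))

    # standard errors conditional on the variance estimate (as in lme4)
    nll_beta = lambda b: -agq.loglik(b, sigma_hat)
    hess = approx_hess(beta_hat, nll_beta)
    cov = np.linalg.pinv(hess)
    bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    params = pd.Series(beta_hat, index=X.columns)
    bse = pd.Series(bse, index=X.columns)
    modes = agq.posterior_modes(beta_hat, sigma_hat) if sigma_hat > 0 else np.zeros(len(labels))
    return GlmmFit(
        spec=spec,
        params=params,
        bse=bse,
        tvalues=params / bse,
        re_var=float(sigma_hat**2),
        re_intercepts=pd.Series(modes, index=labels),
        loglik=float(ll),
        n_rows=len(y),
        converged=ok,
        extra={"trials": trials, "n_quad_nodes": n_nodes},
    )


def fit_glmm(
    rows: pd.DataFrame,
    spec: GlmmSpec | None = None,
    n_quad_nodes: int = 15,
    force_zero_re: bool = False,
) -> GlmmFit:
    """Fit one mixed model by maximum likelihood.

    ``force_zero_re`` pins the random-intercept variance at zero, reducing
    the model to an ordinary (fixed-effects only) GLM fit through the same
    likelihood code path.
    """
    spec = spec or GlmmSpec()
    if rows[spec.grouping].nunique() < 2 and not force_zero_re:
        raise ValueError("need at least two individuals for a mixed model")
    X, y, groups = build_design(rows, spec)
    if spec.response == "dd":
        if force_zero_re:
            fit = _ols_fit(X, y, spec)
        else:
            fit = _fit_lmm(X, y, groups, spec)
    else:
        fit = _fit_binomial_glmm(
            X, y, groups, spec, n_nodes=n_quad_nodes, force_zero_re=force_zero_re
        )
    if "ndvi" in X.columns:
        fit.ndvi_range = (float(X["ndvi"].min()), float(X["ndvi"].max()))
    present = [lv for lv in RANK_LEVELS if f"rank[{lv}]" in X.columns]
    fit.rank_levels = tuple(["low"] + present) if present else ("low",)
    return fit


def _ols_fit(X: pd.DataFrame, y: np.ndarray, spec: GlmmSpec) -> GlmmFit:
    """Gaussian ML fit with the random-intercept variance pinned at zero."""
    Xa = X.to_numpy()
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    resid = y - Xa @ beta
    n = len(y)
    s2 = float(resid @ resid) / n  # ML variance
    ll = -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)
    cov = s2 * n / (n - Xa.shape[1]) * np.linalg.pinv(Xa.T @ Xa)
    bse = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
    params = pd.Series(beta, index=X.columns)
    return GlmmFit(
        spec=spec, params=params, bse=bse, tvalues=params / bse, re_var=0.0,
        re_intercepts=pd.Series(dtype=float), loglik=float(ll), n_rows=n,
        converged=True, extra={"residual_var": s2},
    )


def lrt(full: GlmmFit, reduced: GlmmFit) -> LrtResult:
    """Likelihood-ratio chi-square test of nested fixed-effect structures."""
    if full.spec.response != reduced.spec.response:
        raise ValueError("models have different responses")
    if full.n_rows != reduced.n_rows:
        raise ValueError("models were fit to different data")
    if not set(reduced.param_names) <= set(full.param_names):
        raise ValueError("models are not nested")
    df = len(full.param_names) - len(reduced.param_names)
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        return LrtResult(chi2, 0, 1.0)
    from scipy.stats import chi2 as chi2_dist

    return LrtResult(chi2, df, float(chi2_dist.sf(chi2, df)))


def rank_slopes(fit_or_params: GlmmFit | pd.Series) -> dict[str, float]:
    """NDVI slope per rank: beta_ndvi plus that rank's interaction term."""
    params = fit_or_params.params if isinstance(fit_or_params, GlmmFit) else fit_or_params
    if "ndvi" not in params.index:
        raise ValueError("fit has no NDVI term")
    slopes = {"low": float(params["ndvi"])}
    inter = [n for n in params.index if n.startswith("ndvi:rank[")]
    if not inter:
        raise ValueError("fit has no NDVI:rank interaction terms")
    for name in inter:
        lv = name[len("ndvi:rank[") : -1]
        slopes[lv] = float(params["ndvi"] + params[name])
    return slopes


def slope_percent_change(slopes: dict[str, float]) -> float:
    """Percent change of the high-rank NDVI slope relative to low rank,
    rounded to the nearest percent."""
    if "low" not in slopes or "high" not in slopes:
        raise ValueError("need both low and high slopes")
    if slopes["low"] == 0:
        raise ValueError("low-rank slope is zero")
    return float(round(100.0 * (slopes["high"] - slopes["low"]) / slopes["low"]))


def predict_response(
    fit: GlmmFit,
    ndvi_grid: np.ndarray,
    lag_values: tuple[float, float],
    rank: str,
) -> np.ndarray:
    """Population-level predicted response (random intercept at zero) over an
    NDVI grid, with lag covariates held at supplied values."""
    ndvi_grid = np.atleast_1d(np.asarray(ndvi_grid, dtype=float))
    if fit.ndvi_range is not None:
        lo, hi = fit.ndvi_range
        if np.any((ndvi_grid < lo) | (ndvi_grid > hi)):
            warnings.warn("NDVI grid extends beyond the fitted range", stacklevel=2)
    eta = np.zeros_like(ndvi_grid)
    p = fit.params
    eta += p.get("Intercept", 0.0)
    if "ndvi" in p.index:
        eta += p["ndvi"] * ndvi_grid
    if rank != "low":
        eta += p.get(f"rank[{rank}]", 0.0)
        eta += p.get(f"ndvi:rank[{rank}]", 0.0) * ndvi_grid
    eta += p.get("lag1", 0.0) * lag_values[0] + p.get("lag2", 0.0) * lag_values[1]
    return expit(eta) if fit.spec.link == "logit" else eta


def fit_model_suite(rows: pd.DataFrame, response: str = "dd") -> dict:
    """Full model plus the likelihood-ratio ladder.

    Tests: full model against an intercept-plus-random-effect null;
    interaction against main effects only; first lag against no lags;
    second lag against first lag only.
    """
    specs = {
        "full": GlmmSpec(response, FULL_TERMS),
        "no_interaction": GlmmSpec(response, ("ndvi", "rank", "lag1", "lag2")),
        "null": GlmmSpec(response, ()),
        "no_lags": GlmmSpec(response, ("ndvi", "rank", "ndvi:rank")),
        "lag1_only": GlmmSpec(response, ("ndvi", "rank", "ndvi:rank", "lag1")),
    }
    fits = {name: fit_glmm(rows, spec) for name, spec in specs.items()}
    tests = {
        "full_vs_null": lrt(fits["full"], fits["null"]),
        "interaction": lrt(fits["full"], fits["no_interaction"]),
        "lag1": lrt(fits["lag1_only"], fits["no_lags"]),
        "lag2": lrt(fits["full"], fits["lag1_only"]),
    }
    return {"fits": fits, "tests": tests, "slopes": rank_slopes(fits["full"])}


class DielMixedModel(BaseEstimator):
    """Scikit-learn style wrapper around the mixed-model fit.

    Parameters mirror :class:`GlmmSpec`; ``fit`` expects a model-row frame
    with columns ``y``, ``lag1``, ``lag2``, ``ndvi``, ``rank`` and the
    grouping column.  Fitted attributes: ``coef_``, ``bse_``, ``re_var_``,
    ``loglik_``, ``fit_result_``.
    """

    def __init__(
        self,
        response: str = "dd",
        terms: tuple[str, ...] = FULL_TERMS,
        n_quad_nodes: int = 15,
        force_zero_re: bool = False,
    ) -> None:
        self.response = response
        self.terms = terms
        self.n_quad_nodes = n_quad_nodes
        self.force_zero_re = force_zero_re

    def fit(self, rows: pd.DataFrame, y=None):
        spec = GlmmSpec(self.response, tuple(self.terms))
        res = fit_glmm(
            rows, spec, n_quad_nodes=self.n_quad_nodes, force_zero_re=self.force_zero_re
        )
        self.fit_result_ = res
        self.coef_ = res.params
        self.bse_ = res.bse
        self.re_var_ = res.re_var
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        return self

    def predict(self, ndvi, lag_values: tuple[float, float], rank: str = "low"):
        if not hasattr(self, "fit_result_"):
            raise RuntimeError("call fit before predict")
        return predict_response(self.fit_result_, ndvi, lag_values, rank)

    def rank_slopes(self) -> dict[str, float]:
        return rank_slopes(self.fit_result_)
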