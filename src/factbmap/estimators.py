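"""Regression estimators for mapping FACT-B subscales to EQ-5D-5L utility.

Utility indices are bounded above by 1 and typically show a ceiling mass
there, which strains the assumptions of ordinary least squares. Five
estimators are provided, mirroring the methods debate in the mapping
literature:

* **OLS** — ordinary least squares on the raw utility.
* **Tobit** — maximum likelihood for an upper-censored latent normal; the
  ceiling is treated as censoring at 1.
* **Quantile (median) regression** — least absolute deviations (LAD),
  solved exactly as a linear program.
* **CLAD** — Powell's censored least absolute deviations, computed by
  iteratively trimming observations whose fitted value reaches the censor
  point and refitting LAD on the kept set.
* **Logistic quantile regression** — median regression of the logit
  transform h(y) = log((y − y_min)/(y_max − y)), whose back-transformed
  predictions are guaranteed to stay strictly inside (y_min, y_max).

Model specifications are ordered subsets of the five subscales; the
conventional five presets are::

    Model 1: PWB SWB EWB FWB BCS     Model 4: PWB EWB FWB BCS
    Model 2: PWB SWB EWB FWB         Model 5: PWB EWB FWB
    Model 3: PWB FWB BCS

A registry of published coefficient sets (all 25 method × model cells,
development sample n = 238, 4-decimal precision) ships with the package; see
:func:`published_mapping`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog, minimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .errors import (
    CollinearityError,
    ConvergenceError,
    DegenerateLikelihoodError,
    EmptyDesignError,
    RegistryLookupError,
    SchemaError,
    TransformDomainError,
    UndefinedPredictionError,
)
from .scoring import SUBSCALES, SubscaleProfile
from .utilities import TransformBounds, bounds_preset, inverse_logit_transform, logit_transform

logger = logging.getLogger(__name__)

METHODS = ("ols", "tobit", "clad", "quantile", "lqr")
_METHOD_ALIASES = {"logistic_quantile": "lqr", "logistic-quantile": "lqr", "median": "quantile"}


def canonical_method(method: str) -> str:
    m = method.lower()
    m = _METHOD_ALIASES.get(m, m)
    if m not in METHODS:
        raise RegistryLookupError(f"unknown method {method!r}; choose from {METHODS}")
    return m


@dataclass(frozen=True)
class ModelSpec:
    """Ordered covariate set for one mapping model."""

    covariates: tuple[str, ...]
    extra_covariates: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self):
        for c in self.covariates:
            if c not in SUBSCALES:
                raise SchemaError(f"unknown subscale covariate {c!r}")
        if len(set(self.covariates + self.extra_covariates)) != len(self.covariates) + len(
            self.extra_covariates
        ):
            raise SchemaError("duplicate covariate in model spec")

    @property
    def terms(self) -> tuple[str, ...]:
        return self.covariates + self.extra_covariates

    @property
    def p(self) -> int:
        return len(self.terms)


MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(("PWB", "SWB", "EWB", "FWB", "BCS"), name="Model 1"),
    2: ModelSpec(("PWB", "SWB", "EWB", "FWB"), name="Model 2"),
    3: ModelSpec(("PWB", "FWB", "BCS"), name="Model 3"),
    4: ModelSpec(("PWB", "EWB", "FWB", "BCS"), name="Model 4"),
    5: ModelSpec(("PWB", "EWB", "FWB"), name="Model 5"),
}


def model_spec(model_id: int) -> ModelSpec:
    try:
        return MODEL_SPECS[int(model_id)]
    except (KeyError, ValueError):
        raise RegistryLookupError(f"unknown model id {model_id!r}; presets are 1..5") from None


class Cohort:
    """A fitting/validation cohort: subscale scores, observed utility and
    self-assessed performance status (0-4), one row per subject.

    Thin wrapper over a DataFrame with columns ``PWB,SWB,EWB,FWB,BCS``
    (NaN = undefined under the half-rule), ``utility`` (≤ 1) and optionally
    ``status`` plus any extra covariate columns.
    """

    def __init__(self, data: pd.DataFrame, meta: dict | None = None):
        if "utility" not in data.columns:
            raise SchemaError("cohort needs a 'utility' column")
        u = data["utility"].to_numpy(float)
        if np.any(u[np.isfinite(u)] > 1 + 1e-12):
            raise SchemaError("utilities must not exceed 1")
        self.data = data.reset_index(drop=True)
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.data)

    @property
    def utility(self) -> np.ndarray:
        return self.data["utility"].to_numpy(float)

    @property
    def status(self) -> np.ndarray:
        if "status" not in self.data.columns:
            raise SchemaError("cohort has no 'status' column")
        return self.data["status"].to_numpy(int)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class FittedMapping:
    """A fitted (or published) mapping: intercept + per-covariate coefficients.

    For logistic quantile regression the coefficients live on the transformed
    scale and ``bounds`` drives the automatic back-transform in
    :func:`predict`. ``sigma`` is the Tobit scale estimate.
    """

    method: str
    spec: ModelSpec
    intercept: float
    coefficients: dict[str, float]
    sigma: Optional[float] = None
    bounds: Optional[TransformBounds] = None
    n: int = 0
    standard_errors: Optional[dict[str, float]] = None
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.method = canonical_method(self.method)
        missing = [t for t in self.spec.terms if t not in self.coefficients]
        if missing:
            raise SchemaError(f"coefficients missing for {missing}")
        if self.method == "lqr" and self.bounds is None:
            raise SchemaError("logistic-quantile mapping requires transform bounds")

    @property
    def p(self) -> int:
        return self.spec.p

    def linear_index(self, X_terms: np.ndarray) -> np.ndarray:
        beta = np.array([self.coefficients[t] for t in self.spec.terms])
        return self.intercept + X_terms @ beta

    def to_json(self) -> str:
        d = {
            "method": self.method,
            "covariates": list(self.spec.covariates),
            "extra_covariates": list(self.spec.extra_covariates),
            "model_name": self.spec.name,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "sigma": self.sigma,
            "bounds": None if self.bounds is None else [self.bounds.y_min, self.bounds.y_max],
            "n": self.n,
            "p": self.p,
            "standard_errors": self.standard_errors,
            "converged": self.converged,
            "diagnostics": {k: v for k, v in self.diagnostics.items() if _jsonable(v)},
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedMapping":
        d = json.loads(text)
        spec = ModelSpec(
            tuple(d["covariates"]), tuple(d.get("extra_covariates", ())), d.get("model_name", "")
        )
        bounds = d.get("bounds")
        return cls(
            method=d["method"],
            spec=spec,
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            sigma=d.get("sigma"),
            bounds=None if bounds is None else TransformBounds(*bounds),
            n=int(d.get("n", 0)),
            standard_errors=d.get("standard_errors"),
            converged=bool(d.get("converged", True)),
            diagnostics=d.get("diagnostics", {}),
        )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# design construction


def build_design(
    cohort: "Cohort | pd.DataFrame", spec: ModelSpec, outcome: str = "utility"
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (leading intercept column, then spec order) and outcome.

    Rows with any required covariate or the outcome undefined are dropped;
    the dropped count is logged.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    missing_cols = [t for t in spec.terms if t not in df.columns]
    if missing_cols:
        raise SchemaError(f"cohort missing covariate columns {missing_cols}")
    if outcome not in df.columns:
        raise SchemaError(f"cohort missing outcome column {outcome!r}")
    sub = df[list(spec.terms) + [outcome]].astype(float)
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_design: dropped %d of %d rows with undefined values", n_dropped, len(df))
    sub = sub[keep]
    if len(sub) == 0:
        raise EmptyDesignError("no usable rows after dropping undefined covariates/outcome")
    X = np.column_stack([np.ones(len(sub))] + [sub[t].to_numpy() for t in spec.terms])
    y = sub[outcome].to_numpy()
    return X, y


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(f"design matrix is rank-deficient ({X.shape[1]} columns)")


def _as_mapping(
    method: str,
    spec: ModelSpec,
    params: np.ndarray,
    n: int,
    se: np.ndarray | None = None,
    **kw,
) -> FittedMapping:
    coef = {t: float(b) for t, b in zip(spec.terms, params[1:])}
    ses = None
    if se is not None:
        ses = {"const": float(se[0])} | {t: float(s) for t, s in zip(spec.terms, se[1:])}
    return FittedMapping(
        method=method,
        spec=spec,
        intercept=float(params[0]),
        coefficients=coef,
        n=n,
        standard_errors=ses,
        **kw,
    )


def _spec_for_X(X: np.ndarray, spec: ModelSpec | None) -> ModelSpec:
    if spec is not None:
        if spec.p != X.shape[1] - 1:
            raise SchemaError(f"spec has {spec.p} covariates but X has {X.shape[1] - 1}")
        return spec
    return ModelSpec((), tuple(f"x{i}" for i in range(1, X.shape[1])), name="ad hoc")


# ---------------------------------------------------------------------------
# OLS


def fit_ols(X: np.ndarray, y: np.ndarray, spec: ModelSpec | None = None) -> FittedMapping:
    """Ordinary least squares with classical standard errors (statsmodels)."""
    import statsmodels.api as sm

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    spec = _spec_for_X(X, spec)
    return _as_mapping(
        "ols",
        spec,
        res.params,
        len(y),
        se=res.bse,
        diagnostics={"resid_sd": float(np.sqrt(res.scale)), "r_squared": float(res.rsquared)},
    )


# ---------------------------------------------------------------------------
# Tobit (upper-censored normal MLE)


def _tobit_negloglik_grad(theta, X, y, cens, c):
    beta, logsig = theta[:-1], theta[-1]
    s = np.exp(logsig)
    xb = X @ beta
    ll = 0.0
    g_beta = np.zeros(X.shape[1])
    g_logsig = 0.0
    unc = ~cens
    if unc.any():
        r = (y[unc] - xb[unc]) / s
        ll += np.sum(-np.log(s) - 0.5 * np.log(2 * np.pi) - 0.5 * r**2)
        g_beta += X[unc].T @ r / s
        g_logsig += np.sum(r**2 - 1.0)
    if cens.any():
        a = (xb[cens] - c) / s
        ll += np.sum(log_ndtr(a))
        # inverse Mills ratio, computed stably in log space
        w = np.exp(norm.logpdf(a) - log_ndtr(a))
        g_beta += X[cens].T @ w / s
        g_logsig += -np.sum(w * a)
    g = np.append(g_beta, g_logsig)
    n = len(y)  # mean-scale the objective so gradient tolerances are n-free
    return -ll / n, -g / n


def fit_tobit(
    X: np.ndarray,
    y: np.ndarray,
    censor_point: float = 1.0,
    spec: ModelSpec | None = None,
    gtol: float = 1e-8,
) -> FittedMapping:
    """Upper-censored Tobit MLE on (beta, log sigma), started at OLS.

    Observations with ``y == censor_point`` (within 1e-12) contribute the
    normal survival term; the rest the density term. Standard errors come
    from the inverse observed information (finite differences of the
    analytic gradient).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_rank(X)
    if np.any(y > censor_point + 1e-12):
        raise SchemaError("observations above the censor point")
    cens = np.abs(y - censor_point) <= 1e-12
    if cens.all():
        raise DegenerateLikelihoodError("all observations censored; Tobit likelihood degenerate")
    ols0 = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ ols0
    s0 = max(float(np.std(resid, ddof=X.shape[1])), 1e-6)
    theta0 = np.append(ols0, np.log(s0))
    res = minimize(
        _tobit_negloglik_grad,
        theta0,
        args=(X, y, cens, censor_point),
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": 500},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm < 1e-5)
    if not converged:
        raise ConvergenceError(
            "Tobit MLE did not converge",
            {"grad_norm": grad_norm, "message": res.message, "iterations": int(res.nit)},
        )
    theta = res.x
    sigma = float(np.exp(theta[-1]))
    # observed information via central differences of the analytic gradient
    k = len(theta)
    H = np.zeros((k, k))
    eps = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += eps[j]
        tm[j] -= eps[j]
        gp = _tobit_negloglik_grad(tp, X, y, cens, censor_point)[1]
        gm = _tobit_negloglik_grad(tm, X, y, cens, censor_point)[1]
        H[:, j] = (gp - gm) / (2 * eps[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H) / len(y)  # H is information per observation
        se_beta = np.sqrt(np.maximum(np.diag(cov)[:-1], 0.0))
    except np.linalg.LinAlgError:
        se_beta = np.full(k - 1, np.nan)
    spec = _spec_for_X(X, spec)
    return _as_mapping(
        "tobit",
        spec,
        theta[:-1],
        len(y),
        se=se_beta,
        sigma=sigma,
        converged=converged,
        diagnostics={
            "n_censored": int(cens.sum()),
            "censor_point": censor_point,
            "loglik": -float(res.fun) * len(y),
            "grad_norm": grad_norm,
        },
    )


# ---------------------------------------------------------------------------
# quantile / LAD regression via linear programming


def _solve_quantile_lp(X: np.ndarray, y: np.ndarray, tau: float) -> tuple[np.ndarray, float]:
    n, k = X.shape
    # variables: [beta (free, k), u+ (n), u- (n)]
    c = np.concatenate([np.zeros(k), np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = sp.hstack([sp.csr_matrix(X), sp.identity(n), -sp.identity(n)], format="csr")
    bounds = [(None, None)] * k + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise ConvergenceError("quantile LP failed", {"message": res.message})
    beta = res.x[:k]
    return beta, float(res.fun)


def fit_quantile(
    X: np.ndarray, y: np.ndarray, tau: float = 0.5, spec: ModelSpec | None = None
) -> FittedMapping:
    """Quantile regression (default median/LAD), solved exactly as an LP.

    Minimizes the check loss sum(tau * r+ + (1 - tau) * r-). Degenerate LAD
    problems (non-unique minimizers) are resolved deterministically by the
    HiGHS solver's fixed settings; the optimal objective is unique and is
    stored in ``diagnostics['objective']``.
    """
    if not 0 < tau < 1:
        raise SchemaError(f"tau must be in (0, 1), got {tau}")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_rank(X)
    beta, obj = _solve_quantile_lp(X, y, tau)
    spec = _spec_for_X(X, spec)
    return _as_mapping(
        "quantile", spec, beta, len(y), diagnostics={"objective": obj, "tau": tau}
    )


def fit_clad(
    X: np.ndarray,
    y: np.ndarray,
    censor_point: float = 1.0,
    tau: float = 0.5,
    max_iter: int = 50,
    spec: ModelSpec | None = None,
) -> FittedMapping:
    """Powell's censored LAD via iterative trimming.

    Fit LAD on the kept set (initially everything), drop kept observations
    whose fitted value is at or above the censor point, refit, and stop when
    the kept set stabilizes. The kept set is monotone non-increasing, so the
    iteration always terminates; coefficients equal plain median regression
    whenever trimming never activates.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_rank(X)
    keep = np.ones(len(y), bool)
    history = [int(keep.sum())]
    beta = obj = None
    for it in range(1, max_iter + 1):
        if keep.sum() <= X.shape[1]:
            raise DegenerateLikelihoodError(
                f"CLAD trimming left {int(keep.sum())} rows (≤ number of parameters) "
                f"at iteration {it}; kept-set history {history}"
            )
        beta, obj = _solve_quantile_lp(X[keep], y[keep], tau)
        fitted = X @ beta
        new_keep = keep & (fitted < censor_point - 1e-12)
        history.append(int(new_keep.sum()))
        if new_keep.sum() == keep.sum():
            break
        keep = new_keep
    else:
        raise ConvergenceError(
            "CLAD kept set did not stabilize", {"kept_history": history, "max_iter": max_iter}
        )
    spec = _spec_for_X(X, spec)
    return _as_mapping(
        "clad",
        spec,
        beta,
        len(y),
        diagnostics={
            "objective": obj,
            "iterations": it,
            "kept_history": history,
            "n_trimmed": int(len(y) - keep.sum()),
            "censor_point": censor_point,
            "tau": tau,
        },
    )


def fit_logistic_quantile(
    X: np.ndarray,
    y: np.ndarray,
    bounds: TransformBounds,
    tau: float = 0.5,
    spec: ModelSpec | None = None,
) -> FittedMapping:
    """Median regression of the logit-transformed outcome.

    Every outcome must lie strictly inside (y_min, y_max); coefficients are
    on the transformed scale and predictions back-transform automatically.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    inside = bounds.contains(y)
    if not np.all(inside):
        bad = np.flatnonzero(~inside)
        raise TransformDomainError(
            f"{bad.size} outcome value(s) on or outside ({bounds.y_min}, {bounds.y_max}); "
            f"row indices {bad[:10].tolist()}"
        )
    h = logit_transform(y, bounds)
    fit = fit_quantile(X, h, tau=tau, spec=spec)
    return FittedMapping(
        method="lqr",
        spec=fit.spec,
        intercept=fit.intercept,
        coefficients=fit.coefficients,
        bounds=bounds,
        n=fit.n,
        diagnostics=fit.diagnostics | {"scale": "logit-transformed"},
    )


# ---------------------------------------------------------------------------
# bootstrap standard errors (CLAD / quantile / logistic quantile)


def bootstrap_se(
    fitter: Callable[[np.ndarray, np.ndarray], FittedMapping],
    X: np.ndarray,
    y: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Nonparametric bootstrap SEs for estimators without closed-form ones.

    ``fitter`` maps (X, y) to a FittedMapping; rows are resampled with
    replacement. Resamples where the fit fails (e.g. degenerate trimming)
    are skipped and counted in the returned ``"_failures"`` entry.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    draws = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            m = fitter(X[idx], y[idx])
        except Exception:
            failures += 1
            continue
        draws.append([m.intercept] + [m.coefficients[t] for t in m.spec.terms])
    if len(draws) < 2:
        raise ConvergenceError("bootstrap produced fewer than 2 successful fits")
    arr = np.asarray(draws)
    sds = arr.std(axis=0, ddof=1)
    m0 = fitter(X, y)
    out = {"const": float(sds[0])}
    out |= {t: float(s) for t, s in zip(m0.spec.terms, sds[1:])}
    out["_failures"] = failures
    return out


# ---------------------------------------------------------------------------
# prediction


def predict(
    mapping: FittedMapping,
    profile: "SubscaleProfile | Mapping[str, float] | pd.DataFrame",
) -> float | np.ndarray:
    """Predicted utility for one profile or a DataFrame of profiles.

    OLS/Tobit/CLAD/quantile predictions are the linear index (the Tobit
    latent index may exceed 1); logistic-quantile predictions are the inverse
    logit transform of the linear index and therefore always lie strictly
    inside (y_min, y_max).
    """
    terms = mapping.spec.terms
    if isinstance(profile, pd.DataFrame):
        missing = [t for t in terms if t not in profile.columns]
        if missing:
            raise UndefinedPredictionError(f"profile table missing covariates {missing}")
        Xt = profile[list(terms)].to_numpy(float)
        if np.isnan(Xt).any():
            raise UndefinedPredictionError("undefined covariate value in profile table")
        eta = mapping.linear_index(Xt)
        return inverse_logit_transform(eta, mapping.bounds) if mapping.method == "lqr" else eta
    if isinstance(profile, SubscaleProfile):
        values = profile.as_dict()
    else:
        values = dict(profile)
    row = []
    for t in terms:
        v = values.get(t)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise UndefinedPredictionError(f"covariate {t} undefined for this profile")
        row.append(float(v))
    eta = float(mapping.linear_index(np.asarray([row]))[0])
    if mapping.method == "lqr":
        return float(inverse_logit_transform(eta, mapping.bounds))
    return eta


# ---------------------------------------------------------------------------
# published-coefficient registry


_N_DEVELOPMENT = 238  # development-sample size behind the published registry


def _load_registry() -> tuple[pd.DataFrame, pd.DataFrame]:
    base = resources.files("factbmap.data")
    with base.joinpath("published_coefficients.csv").open("rb") as fh:
        coef = pd.read_csv(fh)
    with base.joinpath("published_gof.csv").open("rb") as fh:
        gof = pd.read_csv(fh)
    return coef, gof


_REGISTRY_CACHE: tuple[pd.DataFrame, pd.DataFrame] | None = None


def _registry() -> tuple[pd.DataFrame, pd.DataFrame]:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        _REGISTRY_CACHE = _load_registry()
    return _REGISTRY_CACHE


def published_mapping(method: str, model_id: int) -> FittedMapping:
    """Published coefficient set for (method, model) — 25 cells, 4-decimal
    precision, development n = 238. Logistic-quantile entries carry the
    Japanese-preset transform bounds."""
    m = canonical_method(method)
    spec = model_spec(model_id)
    coef, _ = _registry()
    rows = coef[(coef["method"] == m) & (coef["model"] == int(model_id))]
    if rows.empty:
        raise RegistryLookupError(f"no published mapping for ({method}, Model {model_id})")
    values = dict(zip(rows["term"], rows["estimate"].astype(float)))
    intercept = values.pop("const")
    if set(values) != set(spec.covariates):
        raise RegistryLookupError(
            f"registry terms {sorted(values)} do not match {spec.covariates}"
        )
    return FittedMapping(
        method=m,
        spec=spec,
        intercept=intercept,
        coefficients=values,
        bounds=bounds_preset("japanese") if m == "lqr" else None,
        n=_N_DEVELOPMENT,
        diagnostics={"source": "published registry (development sample)"},
    )


def published_gof(method: str, model_id: int) -> dict[str, float]:
    """Published goodness-of-fit row (r2, adj_r2, mse, mad) for one cell."""
    m = canonical_method(method)
    _, gof = _registry()
    rows = gof[(gof["method"] == m) & (gof["model"] == int(model_id))]
    if rows.empty:
        raise RegistryLookupError(f"no published GOF for ({method}, Model {model_id})")
    r = rows.iloc[0]
    return {"r2": float(r.r2), "adj_r2": float(r.adj_r2), "mse": float(r.mse), "mad": float(r.mad)}


def published_followup_means() -> pd.DataFrame:
    """Published follow-up mean utilities by performance-status group
    (observed row plus models 3-5 for every method)."""
    with resources.files("factbmap.data").joinpath("followup_status_means.csv").open("rb") as fh:
        return pd.read_csv(fh)


_FITTERS: dict[str, Callable] = {}


def fit(
    method: str,
    cohort: "Cohort | pd.DataFrame",
    model_id: int | ModelSpec = 4,
    outcome: str = "utility",
    **kwargs,
) -> FittedMapping:
    """Fit ``method`` on a cohort under a model preset (or explicit spec).

    Logistic quantile requires ``bounds=`` (or a ``bounds_preset_name=``);
    other methods accept their respective keyword options.
    """
    m = canonical_method(method)
    spec = model_id if isinstance(model_id, ModelSpec) else model_spec(model_id)
    X, y = build_design(cohort, spec, outcome=outcome)
    if m == "ols":
        return fit_ols(X, y, spec=spec, **kwargs)
    if m == "tobit":
        return fit_tobit(X, y, spec=spec, **kwargs)
    if m == "quantile":
        return fit_quantile(X, y, spec=spec, **kwargs)
    if m == "clad":
        return fit_clad(X, y, spec=spec, **kwargs)
    if m == "lqr":
        if "bounds" not in kwargs:
            preset = kwargs.pop("bounds_preset_name", None)
            if preset is None:
                raise SchemaError("logistic quantile needs bounds= or bounds_preset_name=")
            kwargs["bounds"] = bounds_preset(preset)
        return fit_logistic_quantile(X, y, spec=spec, **kwargs)
    raise RegistryLookupError(method)
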