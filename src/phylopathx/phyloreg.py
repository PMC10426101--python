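"""Phylogenetic regression: generalised least squares with an estimated
correlation parameter (Pagel's lambda or an OU-style alpha), a bivariate
screening table, and an approximate phylogenetic logistic fit.

The PGLS estimator is beta = (X' S^-1 X)^-1 X' S^-1 y with S built from the
tree's Brownian covariance under the chosen transform, and the transform
parameter set to its maximum-profile-likelihood value on a bounded search
(lambda in [0, 1]; alpha in [1e-6, alpha_max]).  Wald t-tests use
n_used - p_params degrees of freedom.  Binary responses are handled by the
linear 0/1 GLS by default -- the convention of regression-based path
analysis on binary data -- with a logistic variant available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.linalg import cho_factor, cho_solve

from .treeio import Phylogeny

__all__ = [
    "RegressionSpec",
    "FitResult",
    "pgls_fit",
    "bivariate_screen",
    "phylo_logistic_fit",
]

P_FLOOR = 1e-16  # p-values are clamped above this before any log
_GRID_POINTS = 21


@dataclass
class RegressionSpec:
    """What to regress on what, and how the phylogeny enters.

    ``conditioning`` variables are appended to the predictors (they are in
    the design matrix but are typically nuisance terms of a d-separation
    test).  ``fixed_parameter`` pins the correlation parameter instead of
    estimating it.
    """

    response: str
    predictors: Sequence[str] = ()
    conditioning: Sequence[str] = ()
    transform: str = "lambda"  # or "ou"
    binary_method: str = "linear"  # or "logistic"
    fixed_parameter: float | None = None
    alpha_max: float = 50.0

    def __post_init__(self):
        self.predictors = list(self.predictors)
        self.conditioning = list(self.conditioning)
        if self.response in self.predictors or self.response in self.conditioning:
            raise ValueError("response cannot also be a predictor")
        if self.transform not in ("lambda", "ou"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def design_vars(self) -> list[str]:
        return list(self.predictors) + list(self.conditioning)


@dataclass
class FitResult:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    correlation_parameter: float
    transform: str
    log_likelihood: float
    n_used: int
    df_resid: int
    method: str = "pgls"
    warnings: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return self.coefficients[name]


def _prepare_data(traits: pd.DataFrame, tree: Phylogeny, spec: RegressionSpec):
    cols = [spec.response] + spec.design_vars
    missing_cols = [c for c in cols if c not in traits.columns]
    if missing_cols:
        raise KeyError(f"variables not in trait table: {missing_cols}")
    sub = traits[cols].dropna()
    offenders = sorted(set(sub.index) - set(tree.tips))
    if offenders:
        raise ValueError(f"taxa not on the tree: {offenders}")
    labels = [t for t in tree.tips if t in set(sub.index)]
    sub = sub.loc[labels]
    n = len(sub)
    p = len(spec.design_vars) + 1
    if n < p + 1:
        raise ValueError(f"only {n} complete taxa for {p} parameters; need >= {p + 1}")
    y = sub[spec.response].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("zero variance response")
    X = np.column_stack([np.ones(n)] + [sub[v].to_numpy(dtype=float) for v in spec.design_vars])
    _check_rank(X, ["(intercept)"] + spec.design_vars)
    return labels, y, X


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * X.shape[0] * np.finfo(float).eps * 100
    bad = [names[i] for i in range(len(names)) if diag[i] <= tol]
    if bad:
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _sigma(transform: str, param: float, brown: np.ndarray, pat: np.ndarray) -> np.ndarray:
    if transform == "lambda":
        s = brown * param
        np.fill_diagonal(s, np.diag(brown))
    else:  # ou
        sd = np.sqrt(np.diag(brown))
        s = np.outer(sd, sd) * np.exp(-param * pat)
        np.fill_diagonal(s, np.diag(brown))
    return s


def _gls(y: np.ndarray, X: np.ndarray, sigma: np.ndarray):
    try:
        c, low = cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError:
        # nearly coincident tips make the covariance numerically semidefinite
        jitter = 1e-8 * float(np.mean(np.diag(sigma)))
        c, low = cho_factor(sigma + jitter * np.eye(len(sigma)), lower=True)
    si_y = cho_solve((c, low), y)
    si_X = cho_solve((c, low), X)
    xtsx = X.T @ si_X
    beta = np.linalg.solve(xtsx, X.T @ si_y)
    resid = y - X @ beta
    si_r = cho_solve((c, low), resid)
    rss = float(resid @ si_r)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return beta, rss, logdet, xtsx


def _profile_ll(y, X, sigma) -> float:
    n = len(y)
    _, rss, logdet, _ = _gls(y, X, sigma)
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)


def _optimise_parameter(y, X, brown, pat, transform: str, alpha_max: float):
    lo, hi = (0.0, 1.0) if transform == "lambda" else (1e-6, alpha_max)

    def nll(theta: float) -> float:
        return -_profile_ll(y, X, _sigma(transform, theta, brown, pat))

    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = np.array([nll(t) for t in grid])
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    if a == b:
        return float(grid[k]), -float(vals[k])
    res = optimize.minimize_scalar(nll, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-7})
    if res.fun <= vals[k]:
        return float(res.x), -float(res.fun)
    return float(grid[k]), -float(vals[k])


def pgls_fit(traits: pd.DataFrame, tree: Phylogeny, spec: RegressionSpec) -> FitResult:
    """Fit a phylogenetic GLS regression.

    The trait table is indexed by tip label; rows with any missing value in
    the involved variables are dropped (listwise deletion).  The correlation
    parameter is profiled out by maximum likelihood unless
    ``spec.fixed_parameter`` is set.
    """
    labels, y, X = _prepare_data(traits, tree, spec)
    brown = tree.subset_covariance(labels)
    pat = tree.subset_patristic(labels)
    n, p = X.shape

    if spec.fixed_parameter is not None:
        param = float(spec.fixed_parameter)
        _validate_param(spec.transform, param, spec.alpha_max)
        ll = _profile_ll(y, X, _sigma(spec.transform, param, brown, pat))
    else:
        param, ll = _optimise_parameter(y, X, brown, pat, spec.transform, spec.alpha_max)

    sigma = _sigma(spec.transform, param, brown, pat)
    beta, rss, _, xtsx = _gls(y, X, sigma)
    df = n - p
    s2 = rss / df
    cov_beta = s2 * np.linalg.inv(xtsx)
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = np.clip(2.0 * stats.t.sf(np.abs(tvals), df), P_FLOOR, 1.0)

    names = ["(intercept)"] + spec.design_vars
    return FitResult(
        coefficients=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        p_values=dict(zip(names, pvals.tolist())),
        correlation_parameter=param,
        transform=spec.transform,
        log_likelihood=ll,
        n_used=n,
        df_resid=df,
        method="pgls",
    )


def _validate_param(transform: str, param: float, alpha_max: float) -> None:
    if transform == "lambda" and not 0.0 <= param <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {param}")
    if transform == "ou" and not 0.0 <= param <= alpha_max:
        raise ValueError(f"alpha must lie in [0, {alpha_max}], got {param}")


def bivariate_screen(
    traits: pd.DataFrame,
    tree: Phylogeny,
    response: str,
    candidates: Sequence[str],
    transform: str = "lambda",
    binary_method: str = "linear",
) -> pd.DataFrame:
    """One single-predictor PGLS fit per candidate, with per-fit listwise
    deletion, sorted by p-value and flagged at 0.05 / 0.01.

    Failures are reported per candidate in the ``error`` column rather than
    aborting the screen.
    """
    if response in traits.columns:
        resp = traits[response].dropna()
        if len(resp) and np.std(resp.to_numpy(dtype=float)) == 0:
            raise ValueError("zero variance response")
    rows = []
    for cand in candidates:
        rec = {"variable": cand, "beta": np.nan, "se": np.nan, "p": np.nan,
               "parameter": np.nan, "n": 0, "sig_05": False, "sig_01": False,
               "error": ""}
        try:
            spec = RegressionSpec(
                response=response, predictors=[cand], transform=transform,
                binary_method=binary_method,
            )
            fit = pgls_fit(traits, tree, spec)
            rec.update(
                beta=fit.coefficients[cand],
                se=fit.standard_errors[cand],
                p=fit.p_values[cand],
                parameter=fit.correlation_parameter,
                n=fit.n_used,
                sig_05=fit.p_values[cand] < 0.05,
                sig_01=fit.p_values[cand] < 0.01,
            )
        except Exception as exc:
            rec["error"] = str(exc)
        rows.append(rec)
    out = pd.DataFrame(rows, columns=["variable", "beta", "se", "p", "parameter",
                                      "n", "sig_05", "sig_01", "error"])
    return out.sort_values("p", na_position="last", kind="mergesort").reset_index(drop=True)


def phylo_logistic_fit(traits: pd.DataFrame, tree: Phylogeny, spec: RegressionSpec) -> FitResult:
    """Approximate phylogenetic logistic regression for a strictly 0/1 response.

    A quasi-likelihood IRLS on the latent scale: the working covariance is
    ``W^1/2 R W^1/2`` with ``R`` the phylogenetic correlation matrix under
    the spec's transform at ``fixed_parameter`` (default 1, i.e. full
    Brownian correlation).  With the parameter at 0 this reduces exactly to
    ordinary logistic IRLS.  Complete separation triggers a warning and a
    Firth-style adjustment of the working response.  Documented as
    approximate; use the linear method for d-separation tests.
    """
    labels, y, X = _prepare_data(traits, tree, spec)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logistic fit requires a strictly 0/1 response")
    brown = tree.subset_covariance(labels)
    pat = tree.subset_patristic(labels)
    param = 1.0 if spec.fixed_parameter is None else float(spec.fixed_parameter)
    _validate_param(spec.transform, param, spec.alpha_max)
    sigma = _sigma(spec.transform, param, brown, pat)
    d = np.sqrt(np.diag(sigma))
    R = sigma / np.outer(d, d)

    msgs: list[str] = []
    beta, cov_beta, separated = _pql_irls(y, X, R, firth=False)
    if separated:
        msgs.append("complete or quasi-complete separation detected; "
                    "Firth-style penalty applied")
        warnings.warn(msgs[-1], UserWarning, stacklevel=2)
        beta, cov_beta, _ = _pql_irls(y, X, R, firth=True)

    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)
    eta = X @ beta
    mu = special.expit(eta)
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-12, 1)) +
                      (1 - y) * np.log(np.clip(1 - mu, 1e-12, 1))))
    names = ["(intercept)"] + spec.design_vars
    return FitResult(
        coefficients=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        p_values=dict(zip(names, pvals.tolist())),
        correlation_parameter=param,
        transform=spec.transform,
        log_likelihood=ll,
        n_used=len(y),
        df_resid=len(y) - X.shape[1],
        method="phylo_logistic",
        warnings=msgs,
    )


def _pql_irls(y, X, R, firth: bool, max_iter: int = 100, tol: float = 1e-10):
    n, p = X.shape
    beta = np.zeros(p)
    separated = False
    info = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        sw = np.sqrt(w)
        V = R * np.outer(sw, sw)
        V[np.diag_indices_from(V)] += 1e-10
        c, low = cho_factor(V, lower=True)
        DX = X * w[:, None]
        Vi_DX = cho_solve((c, low), DX)
        info = DX.T @ Vi_DX
        yy = y.copy()
        if firth:
            xw = X * sw[:, None]
            hat = xw @ np.linalg.solve(xw.T @ xw, xw.T)
            yy = y + np.diag(hat) * (0.5 - mu)
        score = DX.T @ cho_solve((c, low), yy - mu)
        step = np.linalg.solve(info, score)
        beta = beta + step
        if np.max(np.abs(beta)) > 30 and not firth:
            separated = True
            break
        if np.max(np.abs(step)) < tol:
            break
    if not separated and not firth:
        mu = special.expit(X @ beta)
        if np.all((mu > 0.5) == (y > 0.5)) and (np.min(np.abs(mu - 0.5)) > 0.49):
            separated = True
    cov_beta = np.linalg.inv(info)
    return beta, cov_beta, separated
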