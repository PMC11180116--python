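"""Fractional-binomial GLM/GLMM fitting and model-selection machinery.

Responses throughout are continuous proportions in [0, 1] (molar sucrose
share of nectar, fructose share of hexoses, or gaussian d' values). The
binomial family uses the Bernoulli-form log-likelihood with fractional
successes and unit weights,

    l = sum_i [ y_i log mu_i + (1 - y_i) log(1 - mu_i) ],

maximised by iteratively reweighted least squares under a logit link.
Mixed models add nested random intercepts whose marginal likelihood is
evaluated with a Laplace approximation. Model selection offers both
stepwise AIC (direction "both") and exhaustive all-subsets inference with
a delta-AIC < 2 best-model set.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ModelSpec",
    "ModelFit",
    "GlmError",
    "fractional_binomial_loglik",
    "build_design",
    "fit_glm",
    "fit_glmm",
    "pseudo_r2",
    "nakagawa_r2",
    "all_subsets_select",
    "stepwise_aic",
]

MU_CLIP = 1e-10  # fitted-value clip inside IRLS only
MAX_CANDIDATES = 20


class GlmError(ValueError):
    """Invalid model specification or degenerate fit."""


def _logit(p):
    return np.log(p / (1.0 - p))


def _inv_logit(eta):
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class ModelSpec:
    """Declarative model description.

    ``predictors`` are column names in the data frame; categorical columns
    are dummy-coded with the first level as reference. ``random`` lists
    grouping columns from outermost to innermost (e.g. ``["order",
    "family"]`` for family nested in order).
    """

    response: str
    predictors: list[str] = field(default_factory=list)
    random: list[str] = field(default_factory=list)
    family: str = "binomial"  # "binomial" (fractional, logit link) | "gaussian"

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "gaussian"):
            raise GlmError(f"unknown family {self.family!r}")


@dataclass
class ModelFit:
    """Coefficients and fit statistics of a (mixed) GLM."""

    spec: ModelSpec
    coefficients: pd.Series  # logit scale for binomial
    loglik: float
    n: int
    k: int  # parameter count (fixed + variance components [+ resid var])
    fitted: np.ndarray
    random_variances: dict[str, float] = field(default_factory=dict)
    resid_variance: float | None = None  # gaussian only
    converged: bool = True
    response_hash: str = ""
    bse: pd.Series | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def aicc(self) -> float:
        n, k = self.n, self.k
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "predictors": list(self.spec.predictors),
            "random": list(self.spec.random),
            "family": self.spec.family,
            "coefficients": self.coefficients.to_dict(),
            "loglik": self.loglik,
            "aic": self.aic,
            "aicc": self.aicc,
            "n": self.n,
            "k": self.k,
            "random_variances": self.random_variances,
            "converged": self.converged,
        }


def _response_hash(y: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(y, dtype=float).tobytes()).hexdigest()[:12]


def check_same_response(*fits: ModelFit) -> None:
    """AICs compare only across fits of the identical response vector."""
    hashes = {f.response_hash for f in fits}
    if len(hashes) > 1:
        raise GlmError("fits were made on different response vectors; AICs not comparable")


# ---------------------------------------------------------------------------
# Likelihood


def fractional_binomial_loglik(y, mu) -> float:
    """Bernoulli-form log-likelihood with fractional successes, unit weights.

    Exact zeros/ones in ``y`` are fine (the corresponding term is finite as
    long as ``mu`` is interior); ``mu`` exactly at 0 or 1 is an error.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise GlmError("y and mu must have equal length")
    if np.any((y < 0) | (y > 1)):
        raise GlmError("y must lie in [0, 1]")
    if np.any((mu <= 0) | (mu >= 1)):
        raise GlmError("degenerate fitted value: mu must lie strictly in (0, 1)")
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


# ---------------------------------------------------------------------------
# Design matrices


def build_design(
    data: pd.DataFrame, predictors: list[str], add_intercept: bool = True
) -> pd.DataFrame:
    """Numeric design matrix; categoricals dummy-coded, first level reference."""
    cols = []
    if add_intercept:
        cols.append(pd.Series(1.0, index=data.index, name="(Intercept)"))
    for name in predictors:
        if name not in data.columns:
            raise GlmError(f"predictor {name!r} not in data")
        col = data[name]
        if col.isna().any():
            raise GlmError(f"missing values in predictor {name!r}")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            cols.extend(dummies[c] for c in dummies.columns)
        else:
            cols.append(col.astype(float))
    return pd.concat(cols, axis=1)


def _check_rank(X: pd.DataFrame) -> None:
    M = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify aliased columns via incremental rank
        aliased = []
        kept: list[int] = []
        for j in range(M.shape[1]):
            sub = M[:, kept + [j]]
            if np.linalg.matrix_rank(sub) > len(kept):
                kept.append(j)
            else:
                aliased.append(X.columns[j])
        raise GlmError(f"design matrix rank deficient; aliased columns: {aliased}")


# ---------------------------------------------------------------------------
# GLM via IRLS


def _irls(y: np.ndarray, X: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Fractional-binomial logit IRLS; returns (beta, mu, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    # start from the intercept at logit(mean)
    ybar = min(max(y.mean(), MU_CLIP), 1 - MU_CLIP)
    beta[0] = _logit(ybar) if np.allclose(X[:, 0], 1.0) else 0.0
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(_inv_logit(eta), MU_CLIP, 1 - MU_CLIP)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    mu = np.clip(_inv_logit(X @ beta), MU_CLIP, 1 - MU_CLIP)
    return beta, mu, converged


def fit_glm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit a fractional-binomial (logit) or gaussian GLM.

    Raises on missing values, rank deficiency (naming the aliased columns);
    warns when coefficients are large enough to suggest separation.
    """
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise GlmError("missing values in response")
    X = build_design(data, spec.predictors)
    _check_rank(X)
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    if spec.family == "gaussian":
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        resid = y - Xm @ beta
        sigma2 = float(resid @ resid) / n  # ML estimate
        ll = float(-0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0))
        fit = ModelFit(
            spec, pd.Series(beta, index=X.columns), ll, n, p + 1, Xm @ beta,
            resid_variance=sigma2, response_hash=_response_hash(y),
        )
        cov = sigma2 * np.linalg.inv(Xm.T @ Xm) * n / max(n - p, 1)
        fit.bse = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
        return fit
    if np.any((y < 0) | (y > 1)):
        raise GlmError("binomial response must lie in [0, 1]")
    beta, mu, converged = _irls(y, Xm)
    if np.max(np.abs(beta)) > 30:
        warnings.warn(
            "very large coefficients: possible (quasi-)separation; "
            "estimates reported at the IRLS stopping point"
        )
    ll = fractional_binomial_loglik(y, mu)
    w = mu * (1 - mu)
    fisher = Xm.T @ (Xm * w[:, None])
    try:
        cov = np.linalg.inv(fisher)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
    except np.linalg.LinAlgError:
        bse = None
    return ModelFit(
        spec, pd.Series(beta, index=X.columns), ll, n, p, mu,
        converged=converged, response_hash=_response_hash(y), bse=bse,
    )


# ---------------------------------------------------------------------------
# Binomial GLMM via Laplace approximation


def _group_indicator(codes: np.ndarray, n_groups: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_groups))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _laplace_loglik(y, Xm, Z, level_sizes, params, inner_tol=1e-10):
    """Laplace-approximate marginal log-likelihood of a logit GLMM.

    ``params`` = fixed coefficients followed by one log-sd per random level;
    ``Z`` stacks the per-level indicator blocks; ``level_sizes`` gives the
    number of effects per level. Returns (loglik, u_mode).
    """
    p = Xm.shape[1]
    beta = params[:p]
    log_sd = params[p:]
    q = Z.shape[1]
    d_inv = np.concatenate(
        [np.full(m, np.exp(-2.0 * s)) for m, s in zip(level_sizes, log_sd)]
    )
    u = np.zeros(q)
    offset = Xm @ beta
    for _ in range(100):  # Newton on the penalised joint log-density
        eta = offset + Z @ u
        mu = np.clip(_inv_logit(eta), MU_CLIP, 1 - MU_CLIP)
        grad = Z.T @ (y - mu) - d_inv * u
        w = mu * (1 - mu)
        H = Z.T @ (Z * w[:, None])
        H[np.diag_indices_from(H)] += d_inv
        delta = np.linalg.solve(H, grad)
        u = u + delta
        if np.max(np.abs(delta)) < inner_tol:
            break
    eta = offset + Z @ u
    mu = np.clip(_inv_logit(eta), MU_CLIP, 1 - MU_CLIP)
    w = mu * (1 - mu)
    H = Z.T @ (Z * w[:, None])
    H[np.diag_indices_from(H)] += d_inv
    ll_cond = np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
    penalty = 0.5 * np.sum(d_inv * u * u)
    # log det(D^-1) = -sum over effects of 2*log_sd ; Laplace correction
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf, u
    logdet_Dinv = float(np.sum([m * (-2.0 * s) for m, s in zip(level_sizes, log_sd)]))
    ll = ll_cond - penalty + 0.5 * logdet_Dinv - 0.5 * logdet_H
    return float(ll), u


LOG_SD_BOUNDS = (-7.0, 3.0)


def fit_glmm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Random-intercept logit GLMM, Laplace-approximate maximum likelihood.

    ``spec.random`` lists grouping factors outermost first; nested levels are
    entered as separate intercept blocks (order, then family-within-order).
    With a single group at every level the model collapses to ``fit_glm``
    (with a warning). The optimiser is deterministic from a fixed start.
    """
    if spec.family != "binomial":
        raise GlmError("fit_glmm implements the binomial-logit family; use networks"
                       " module models for gaussian mixed fits")
    if not spec.random:
        raise GlmError("no random terms: use fit_glm")
    y = data[spec.response].to_numpy(dtype=float)
    X = build_design(data, spec.predictors)
    _check_rank(X)
    Xm = X.to_numpy(dtype=float)
    blocks, level_sizes, level_names = [], [], []
    parent = None
    for col in spec.random:
        if col not in data.columns:
            raise GlmError(f"grouping column {col!r} not in data")
        # nested coding: group identity is the tuple of this and outer levels
        key = data[col].astype(str) if parent is None else parent + "/" + data[col].astype(str)
        codes, uniq = pd.factorize(key)
        if len(uniq) < 2:
            warnings.warn(f"random level {col!r} has a single group; dropping to GLM")
            return fit_glm(ModelSpec(spec.response, spec.predictors, [], spec.family), data)
        blocks.append(_group_indicator(codes, len(uniq)))
        level_sizes.append(len(uniq))
        level_names.append(col)
        parent = key
    Z = np.hstack(blocks)
    glm_start = fit_glm(ModelSpec(spec.response, spec.predictors, [], "binomial"), data)
    p = Xm.shape[1]
    x0 = np.concatenate([glm_start.coefficients.to_numpy(), np.full(len(level_sizes), np.log(0.5))])

    def neg_ll(params):
        ll, _ = _laplace_loglik(y, Xm, Z, level_sizes, params)
        return -ll

    bounds = [(None, None)] * p + [LOG_SD_BOUNDS] * len(level_sizes)
    res = optimize.minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500})
    params = res.x
    ll, u = _laplace_loglik(y, Xm, Z, level_sizes, params)
    beta = params[:p]
    variances = {name: float(np.exp(2.0 * s)) for name, s in zip(level_names, params[p:])}
    eta = Xm @ beta + Z @ u
    mu = _inv_logit(eta)
    k = p + len(level_sizes)
    # Wald SEs for the fixed effects from the profiled Laplace curvature
    bse = None
    try:
        hess = _numeric_hessian(lambda b: -_laplace_loglik(
            y, Xm, Z, level_sizes, np.concatenate([b, params[p:]]))[0], beta)
        cov = np.linalg.inv(hess)
        bse = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=X.columns)
    except np.linalg.LinAlgError:
        pass
    return ModelFit(
        spec, pd.Series(beta, index=X.columns), float(ll), len(y), k, mu,
        random_variances=variances, converged=bool(res.success),
        response_hash=_response_hash(y), bse=bse,
    )


def _numeric_hessian(f, x, h=1e-4):
    n = x.size
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    _ = f0
    return H


# ---------------------------------------------------------------------------
# Pseudo-R2 and mixed-model R2


def pseudo_r2(fit: ModelFit, null_fit: ModelFit, adjusted: bool = False) -> float:
    """Likelihood-ratio pseudo-R2 (Cox–Snell form, optionally adjusted).

    Unadjusted: R2 = 1 - exp(-(2/n)(l_M - l_0)). Adjusted: divide by
    R2_max = 1 - exp((2/n) l_0) (Nagelkerke rescaling), then apply the
    small-sample correction 1 - (1 - R2)(n-1)/(n-k-1), floored at 0.
    """
    if fit.n != null_fit.n:
        raise GlmError("fit and null must have the same n")
    check_same_response(fit, null_fit)
    if fit.loglik < null_fit.loglik - 1e-9:
        raise GlmError("model worse than null: log-likelihood below the null fit")
    n = fit.n
    r2 = 1.0 - np.exp(-(2.0 / n) * (fit.loglik - null_fit.loglik))
    if not adjusted:
        return float(r2)
    r2_max = 1.0 - np.exp((2.0 / n) * null_fit.loglik)
    if r2_max > 0:
        r2 = r2 / r2_max
    k = fit.k - 1  # predictors beyond the intercept
    if n - k - 1 > 0:
        r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return float(max(r2, 0.0))


def nakagawa_r2(fit: ModelFit, X: pd.DataFrame | None = None) -> tuple[float, float]:
    """Marginal and conditional R2 of a mixed model.

    marginal = var(fixed) / (var(fixed) + sum var(random) + var(resid));
    conditional adds the random variances to the numerator. The residual
    variance is pi^2/3 on the logit scale, or the estimated residual
    variance for gaussian fits.
    """
    var_fixed = float(np.var(_fixed_linear_predictor(fit, X)))
    var_random = float(sum(fit.random_variances.values()))
    if fit.spec.family == "binomial":
        var_resid = np.pi**2 / 3.0
    else:
        if fit.resid_variance is None:
            raise GlmError("gaussian fit lacks a residual variance")
        var_resid = fit.resid_variance
    denom = var_fixed + var_random + var_resid
    return var_fixed / denom, (var_fixed + var_random) / denom


def _fixed_linear_predictor(fit: ModelFit, X: pd.DataFrame | None) -> np.ndarray:
    if X is None:
        raise GlmError("nakagawa_r2 needs the design matrix (pass build_design output)")
    return X.to_numpy(dtype=float) @ fit.coefficients.to_numpy()


# ---------------------------------------------------------------------------
# Model selection


def _fit_subset(response, subset, data, family) -> ModelFit:
    return fit_glm(ModelSpec(response, list(subset), [], family), data)


@dataclass
class SubsetSelection:
    best_models: list[ModelFit]  # delta AIC < 2, sorted
    predictor_union: list[str]
    table: pd.DataFrame  # all subsets: predictors, k, loglik, AIC, AICc, delta


def all_subsets_select(
    candidates: list[str],
    data: pd.DataFrame,
    spec: ModelSpec,
    criterion: str = "aic",
    delta: float = 2.0,
) -> SubsetSelection:
    """Exhaustive multimodel inference: fit every predictor subset.

    Returns the set of models within ``delta`` of the best AIC (or AICc) and
    the union of their predictors. Ordering is deterministic: criterion
    ascending, then parameter count, then the lexical predictor tuple.
    """
    if len(candidates) > MAX_CANDIDATES:
        raise GlmError(
            f"{len(candidates)} candidates exceed the all-subsets guard of "
            f"{MAX_CANDIDATES}; pre-screen (e.g. stepwise) first"
        )
    if len(set(candidates)) != len(candidates):
        dupes = sorted({c for c in candidates if candidates.count(c) > 1})
        raise GlmError(f"duplicated candidate predictor(s): {dupes}")
    rows, fits = [], []
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            fit = _fit_subset(spec.response, subset, data, spec.family)
            score = fit.aicc if criterion == "aicc" else fit.aic
            rows.append({"predictors": subset, "k": fit.k, "loglik": fit.loglik,
                         "aic": fit.aic, "aicc": fit.aicc, "score": score})
            fits.append(fit)
    table = pd.DataFrame(rows)
    table["delta"] = table["score"] - table["score"].min()
    key = sorted(
        range(len(fits)),
        key=lambda i: (rows[i]["score"], rows[i]["k"], rows[i]["predictors"]),
    )
    best_idx = [i for i in key if table.loc[i, "delta"] < delta]
    best = [fits[i] for i in best_idx]
    union = sorted({p for i in best_idx for p in rows[i]["predictors"]},
                   key=candidates.index)
    table = table.sort_values(["score", "k"], kind="mergesort").reset_index(drop=True)
    return SubsetSelection(best, union, table)


def stepwise_aic(
    candidates: list[str], data: pd.DataFrame, spec: ModelSpec
) -> list[str]:
    """Stepwise selection, direction "both", starting from the intercept.

    At each round the single add or drop that lowers AIC most is taken;
    ties break on the lowest candidate index. Stops when no move improves.
    """
    if len(set(candidates)) != len(candidates):
        dupes = sorted({c for c in candidates if candidates.count(c) > 1})
        raise GlmError(f"duplicated candidate predictor(s): {dupes}")
    selected: list[str] = []
    current = _fit_subset(spec.response, selected, data, spec.family)
    current_aic = current.aic
    improved = True
    while improved:
        improved = False
        moves = []  # (aic, candidate_index, new_selected)
        for c in candidates:
            if c not in selected:
                trial = selected + [c]
            else:
                trial = [s for s in selected if s != c]
            fit = _fit_subset(spec.response, trial, data, spec.family)
            moves.append((fit.aic, candidates.index(c), trial))
        moves.sort(key=lambda t: (t[0], t[1]))
        if moves and moves[0][0] < current_aic - 1e-10:
            current_aic = moves[0][0]
            selected = sorted(moves[0][2], key=candidates.index)
            improved = True
    return selected
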