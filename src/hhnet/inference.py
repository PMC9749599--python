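"""Per-round survey-weighted and pooled multilevel logistic inference.

Each structural or compositional exposure is analysed one at a time
(the measures are highly collinear by construction): a crude model with
the exposure alone and an adjusted model adding the fixed covariate set
(woman's age, education, residence, partner coresidence, sex of head,
wealth index, earnings type). Per-round models maximise the
survey-weighted log-likelihood sum_i w_i [y_i log p_i + (1-y_i)
log(1-p_i)] (statsmodels GLM) with linearised sandwich variance
clustered on the primary sampling unit. The pooled model is a
random-intercept logistic with a Gaussian intercept per survey round,
fitted by maximum likelihood with the group integrals evaluated by
adaptive Gauss-Hermite quadrature; observations are equally weighted in
the pooled model.

Fits are converted to average marginal effects (AME, reported in
percentage points): for categorical exposures the mean discrete change
in predicted probability from the reference level with all other
covariates at observed values, for continuous exposures the mean of
beta * p * (1 - p). Confidence intervals use the delta method;
random effects are evaluated at zero by default, with an option to
integrate over the fitted Gaussian instead.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from statsmodels.tools import numdiff

from hhnet.errors import ConvergenceError, HHNetError

#: encoding registry: reference level first for categoricals
CATEGORICAL_LEVELS: dict[str, tuple] = {
    "effective_size_band": ("low", "high"),
    "iqv_education_band": ("low", "high"),
    "coresidence_partner": ("living_with_woman", "stays_elsewhere"),
    "respondent_type": ("maternal", "nonmaternal"),
    "mother_education": ("none", "primary", "secondary_plus"),
    "residence": ("rural", "urban"),
    "head_sex": ("male", "female"),
    "wealth_index": ("poor", "middle", "rich"),
    "earnings_type": ("not_working", "working_unpaid", "paid"),
}

#: 0/1 flags analysed as discrete-change exposures
BINARY_VARIABLES = {"defacto_diversity", "dejure_diversity"}

DEFAULT_COVARIATES = [
    "mother_age",
    "mother_education",
    "residence",
    "coresidence_partner",
    "head_sex",
    "wealth_index",
    "earnings_type",
]

DEFAULT_EXPOSURES = [
    "degree",
    "effective_size_band",
    "constraint",
    "age_sd",
    "iqv_sex",
    "iqv_kinship",
    "iqv_education_band",
    "defacto_diversity",
    "dejure_diversity",
]


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One model of the grid: a single exposure plus fixed covariates."""

    exposure: str
    covariates: tuple = tuple(DEFAULT_COVARIATES)
    outcome: str = "outcome_introduced"
    weighting: str = "survey_weighted"  # or "unweighted"
    pooling: str = "per_round"  # or "multilevel_pooled"


def term_columns(term: str) -> list[str]:
    """Design column names a variable expands to (dummy encoding)."""
    if term in CATEGORICAL_LEVELS:
        ref, *rest = CATEGORICAL_LEVELS[term]
        return [f"{term}[{lvl}]" for lvl in rest]
    return [term]


def build_design(data: pd.DataFrame, terms, outcome: str):
    """Design matrix with intercept, complete-case.

    Returns (X, y, kept_index); categorical terms become treatment
    dummies against their registered reference level.
    """
    used = [outcome, *terms]
    sub = data[used].dropna()
    X = pd.DataFrame(index=sub.index)
    X["const"] = 1.0
    for term in terms:
        if term in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[term]
            observed = set(sub[term].astype(str))
            unknown = observed - set(map(str, levels))
            if unknown:
                raise HHNetError(f"{term}: unexpected level(s) {sorted(unknown)}")
            for lvl in levels[1:]:
                X[f"{term}[{lvl}]"] = (sub[term].astype(str) == str(lvl)).astype(float)
        else:
            X[term] = sub[term].astype(float)
    y = sub[outcome].astype(float)
    return X, y, sub.index


@dataclasses.dataclass
class ModelResult:
    """A fitted logistic model with everything AMEs need."""

    params: pd.Series
    cov: pd.DataFrame
    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray
    n_used: int
    converged: bool
    kind: str  # "glm" | "glmm"
    exposure: str | None = None
    sigma2_round: float | None = None
    logsigma_index: int | None = None  # position of log-sigma in cov, glmm only

    def odds_ratios(self, terms=None) -> pd.DataFrame:
        """OR, 95% CI and p-value per design column (const excluded)."""
        cols = [c for c in self.params.index if c != "const" and c != "__logsigma__"]
        if terms is not None:
            keep = {c for t in terms for c in term_columns(t)}
            cols = [c for c in cols if c in keep]
        beta = self.params[cols]
        se = pd.Series(np.sqrt(np.diag(self.cov.loc[cols, cols])), index=cols)
        from scipy.stats import norm

        z = beta / se
        return pd.DataFrame(
            {
                "beta": beta,
                "se": se,
                "or": np.exp(beta),
                "ci_low": np.exp(beta - 1.959963984540054 * se),
                "ci_high": np.exp(beta + 1.959963984540054 * se),
                "p_value": 2 * norm.sf(np.abs(z)),
            }
        )

    def beta_vector(self) -> np.ndarray:
        return self.params[[c for c in self.params.index if c != "__logsigma__"]].to_numpy()


def _check_outcome(y: np.ndarray):
    if len(np.unique(y)) < 2:
        raise ConvergenceError("outcome has a single class; model not estimable")


def fit_weighted_logistic(
    data: pd.DataFrame,
    exposure: str,
    covariates=(),
    outcome: str = "outcome_introduced",
    weighted: bool = True,
    cluster_col: str = "cluster_id",
) -> ModelResult:
    """Survey-weighted logistic fit with cluster-robust variance.

    The crude model passes ``covariates=()``; the adjusted model the
    fixed covariate list. With all weights equal the point estimates
    coincide with the unweighted fit.
    """
    terms = [exposure, *covariates]
    X, y, idx = build_design(data, terms, outcome)
    yv = y.to_numpy()
    _check_outcome(yv)
    for col in term_columns(exposure):
        if col in X and X[col].nunique() < 2:
            raise ConvergenceError(f"exposure column {col!r} has zero variance")
    w = data.loc[idx, "weight"].to_numpy(dtype=float) if weighted else np.ones(len(yv))
    groups = data.loc[idx, cluster_col].astype(str).to_numpy()

    model = sm.GLM(yv, X, family=sm.families.Binomial(), var_weights=w)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(np.unique(groups)) > 1:
                fit = model.fit(cov_type="cluster", cov_kwds={"groups": pd.Series(groups)})
            else:
                fit = model.fit(cov_type="HC1")
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ConvergenceError(f"weighted logistic fit failed: {exc}") from exc
    params = pd.Series(fit.params, index=X.columns)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 15:
        raise ConvergenceError(
            f"separation suspected: max |beta| = {np.abs(params).max():.2f}"
        )
    return ModelResult(
        params=params,
        cov=pd.DataFrame(fit.cov_params(), index=X.columns, columns=X.columns),
        X=X,
        y=yv,
        weights=w,
        n_used=len(yv),
        converged=bool(fit.converged),
        kind="glm",
        exposure=exposure,
    )


# ---------------------------------------------------------------------------
# random-intercept logistic (multilevel pooled model)
# ---------------------------------------------------------------------------


def _group_loglik(eta_g: np.ndarray, y_g: np.ndarray, sigma: float, gh_x, gh_w) -> float:
    """log integral over the group's Gaussian random intercept,
    adaptive Gauss-Hermite around the integrand's mode."""
    # Newton for the mode of h(u) = sum log p_i(u) - u^2 / (2 sigma^2)
    u = 0.0
    for _ in range(50):
        p = expit(eta_g + u)
        g = np.sum(y_g - p) - u / sigma**2
        h = -np.sum(p * (1 - p)) - 1.0 / sigma**2
        step = g / h
        u -= step
        if abs(step) < 1e-12:
            break
    p = expit(eta_g + u)
    h = -np.sum(p * (1 - p)) - 1.0 / sigma**2
    s = 1.0 / np.sqrt(-h)
    nodes = u + s * gh_x  # hermegauss: weight exp(-x^2/2)
    # log integrand at nodes (Bernoulli loglik + Gaussian density)
    eta_nodes = eta_g[None, :] + nodes[:, None]
    ll = np.sum(
        np.where(y_g[None, :] > 0, -np.logaddexp(0, -eta_nodes), -np.logaddexp(0, eta_nodes)),
        axis=1,
    )
    log_phi = -0.5 * (nodes / sigma) ** 2 - 0.5 * np.log(2 * np.pi * sigma**2)
    # int f(u) du ~= s * sum_k w_k exp(x_k^2/2) f(u_k)
    return float(logsumexp(np.log(gh_w) + 0.5 * gh_x**2 + ll + log_phi) + np.log(s))


def _plain_logistic_newton(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Unweighted logistic ML by Newton-Raphson (used for the pinned
    sigma=0 limiting case and as the GLMM starting value)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        g = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular Hessian in logistic fit") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, H
    raise ConvergenceError("logistic Newton iteration did not converge")


def fit_multilevel_logistic(
    data: pd.DataFrame,
    exposure: str,
    covariates=(),
    outcome: str = "outcome_introduced",
    group_col: str = "survey_round",
    n_quad: int = 12,
    fix_sigma: float | None = None,
    max_iter: int = 200,
) -> ModelResult:
    """Random-intercept logistic over survey rounds, ML via adaptive
    Gauss-Hermite quadrature. Observations are equally weighted.

    With a single round present the model falls back to ordinary
    logistic regression with a warning. ``fix_sigma=0`` pins the
    random-effect variance to zero (exactly the pooled ordinary
    logistic likelihood).
    """
    terms = [exposure, *covariates]
    X, y, idx = build_design(data, terms, outcome)
    yv = y.to_numpy()
    _check_outcome(yv)
    Xv = X.to_numpy()
    groups = data.loc[idx, group_col].astype(str).to_numpy()
    group_ids = np.unique(groups)

    def _wrap_plain(note: str | None = None) -> ModelResult:
        if note:
            warnings.warn(note)
        beta, H = _plain_logistic_newton(Xv, yv)
        cov = np.linalg.inv(H)
        return ModelResult(
            params=pd.Series(beta, index=X.columns),
            cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
            X=X,
            y=yv,
            weights=np.ones(len(yv)),
            n_used=len(yv),
            converged=True,
            kind="glmm",
            exposure=exposure,
            sigma2_round=0.0 if fix_sigma == 0.0 else None,
        )

    if len(group_ids) < 2:
        return _wrap_plain("single survey round: falling back to ordinary logistic")
    if fix_sigma is not None and fix_sigma == 0.0:
        return _wrap_plain()

    gh_x, gh_w = hermegauss(n_quad)
    slices = [np.flatnonzero(groups == g) for g in group_ids]
    k = Xv.shape[1]
    fixed = fix_sigma is not None

    def nll(theta):
        beta = theta[:k]
        sigma = fix_sigma if fixed else float(np.exp(theta[k]))
        eta = Xv @ beta
        return -sum(_group_loglik(eta[s], yv[s], sigma, gh_x, gh_w) for s in slices)

    beta0, _ = _plain_logistic_newton(Xv, yv)
    x0 = np.append(beta0, []) if fixed else np.append(beta0, np.log(0.3))
    try:
        res = minimize(nll, x0, method="BFGS", jac="3-point",
                       options={"gtol": 1e-7, "maxiter": max_iter})
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ConvergenceError(f"multilevel fit failed: {exc}") from exc
    grad_norm = float(np.max(np.abs(res.jac)))
    if not np.all(np.isfinite(res.x)) or grad_norm > 1e-2:
        raise ConvergenceError(
            f"multilevel fit did not converge (max |gradient| = {grad_norm:.3g})"
        )
    H = numdiff.approx_hess(res.x, nll)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular Hessian at the GLMM optimum") from exc

    names = list(X.columns) + ([] if fixed else ["__logsigma__"])
    params = pd.Series(res.x, index=names)
    sigma = fix_sigma if fixed else float(np.exp(res.x[k]))
    return ModelResult(
        params=params,
        cov=pd.DataFrame(cov, index=names, columns=names),
        X=X,
        y=yv,
        weights=np.ones(len(yv)),
        n_used=len(yv),
        converged=True,
        kind="glmm",
        exposure=exposure,
        sigma2_round=float(sigma**2),
        logsigma_index=None if fixed else k,
    )


# ---------------------------------------------------------------------------
# average marginal effects
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MarginalEffect:
    """AME in percentage points for one exposure level (or per unit)."""

    variable: str
    level: str | None
    me_pp: float
    se_pp: float
    ci95_pp: tuple
    kind: str  # "discrete_change" | "average_derivative"


def _integrated_expit(eta: np.ndarray, sigma: float, gh_x, gh_w) -> np.ndarray:
    """E_u expit(eta + u), u ~ N(0, sigma^2), by Gauss-Hermite."""
    vals = expit(eta[None, :] + sigma * gh_x[:, None])
    return (gh_w[:, None] * vals).sum(axis=0) / gh_w.sum()


def average_marginal_effect(
    result: ModelResult,
    variable: str | None = None,
    re_treatment: str = "zero",
    n_quad: int = 12,
) -> list[MarginalEffect]:
    """Delta-method AMEs (x100, percentage points) for one variable.

    Categorical / binary variables: mean discrete change in predicted
    probability from the reference level, all other covariates at
    observed values. Continuous: mean of beta * p * (1 - p).
    Averages use the model's estimation weights. For multilevel fits
    the random intercept is evaluated at zero (``re_treatment="zero"``)
    or integrated over the fitted Gaussian (``"integrate"``).
    """
    variable = variable or result.exposure
    cols = term_columns(variable)
    if not all(c in result.params.index for c in cols):
        raise HHNetError(f"variable {variable!r} not in the fitted design")
    X = result.X.to_numpy()
    names = list(result.params.index)
    w = result.weights / result.weights.sum()
    theta_hat = result.params.to_numpy()
    ls_idx = result.logsigma_index
    integrate = result.kind == "glmm" and re_treatment == "integrate" and ls_idx is not None
    gh_x, gh_w = hermegauss(n_quad)

    def predict(Xm, theta):
        beta = theta[: X.shape[1]]
        eta = Xm @ beta
        if integrate:
            return _integrated_expit(eta, float(np.exp(theta[ls_idx])), gh_x, gh_w)
        return expit(eta)

    is_categorical = variable in CATEGORICAL_LEVELS or variable in BINARY_VARIABLES
    out = []
    if is_categorical:
        # a 0/1 flag is a one-dummy discrete change with no level label
        levels = CATEGORICAL_LEVELS.get(variable, (None, None))
        dummy_idx = [names.index(c) for c in cols]
        X0 = X.copy()
        X0[:, dummy_idx] = 0.0
        for col, level in zip(cols, levels[1:]):
            X1 = X0.copy()
            X1[:, names.index(col)] = 1.0

            def g(theta, X1=X1):
                return 100.0 * float(w @ (predict(X1, theta) - predict(X0, theta)))

            me = g(theta_hat)
            grad = numdiff.approx_fprime(theta_hat, g, centered=True)
            se = float(np.sqrt(grad @ result.cov.to_numpy() @ grad))
            out.append(
                MarginalEffect(
                    variable=variable,
                    level=None if level is None else str(level),
                    me_pp=me,
                    se_pp=se,
                    ci95_pp=(me - 1.959963984540054 * se, me + 1.959963984540054 * se),
                    kind="discrete_change",
                )
            )
    else:
        j = names.index(variable)

        def g(theta):
            p = predict(X, theta)
            return 100.0 * float(theta[j] * (w @ (p * (1 - p))))

        me = g(theta_hat)
        grad = numdiff.approx_fprime(theta_hat, g, centered=True)
        se = float(np.sqrt(grad @ result.cov.to_numpy() @ grad))
        out.append(
            MarginalEffect(
                variable=variable,
                level=None,
                me_pp=me,
                se_pp=se,
                ci95_pp=(me - 1.959963984540054 * se, me + 1.959963984540054 * se),
                kind="average_derivative",
            )
        )
    return out


# ---------------------------------------------------------------------------
# the model grid
# ---------------------------------------------------------------------------


def run_model_grid(
    data: pd.DataFrame,
    exposures=None,
    covariates=None,
    alpha: float = 0.05,
    n_quad: int = 12,
    re_treatment: str = "zero",
) -> pd.DataFrame:
    """Fit the full exposure grid and return a tidy results table.

    Per exposure: crude and adjusted survey-weighted ORs per round,
    the pooled multilevel adjusted OR, and the pooled AME. Single
    failures (separation, zero variance) are recorded as
    ``converged=False`` rows; the grid continues.
    """
    exposures = list(exposures or DEFAULT_EXPOSURES)
    covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
    rounds = sorted(data["survey_round"].astype(str).unique())
    rows: list[dict] = []

    def emit(exposure, level, rnd, model, est_type, est, lo, hi, p, n, converged, note=""):
        rows.append(
            {
                "exposure": exposure,
                "level": "" if level is None else str(level),
                "round": rnd,
                "model": model,
                "estimate_type": est_type,
                "estimate": est,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": p,
                "significant": bool(p < alpha) if p == p else False,
                "n": n,
                "converged": converged,
                "note": note,
            }
        )

    def emit_or(exposure, rnd, model, result):
        table = result.odds_ratios(terms=[exposure])
        levels = CATEGORICAL_LEVELS.get(exposure, (None,))[1:] or [None]
        for col, level in zip(term_columns(exposure), levels):
            r = table.loc[col]
            emit(exposure, level, rnd, model, "OR", r["or"], r["ci_low"], r["ci_high"],
                 r["p_value"], result.n_used, True)

    def emit_failure(exposure, rnd, model, est_type, exc):
        levels = CATEGORICAL_LEVELS.get(exposure, (None,))[1:] or [None]
        for level in levels:
            emit(exposure, level, rnd, model, est_type, np.nan, np.nan, np.nan,
                 np.nan, 0, False, note=str(exc))

    for exposure in exposures:
        for rnd in rounds:
            sub = data[data["survey_round"].astype(str) == rnd]
            for model_name, covs in (("crude", ()), ("adjusted", tuple(covariates))):
                try:
                    res = fit_weighted_logistic(sub, exposure, covs)
                    emit_or(exposure, rnd, model_name, res)
                except (ConvergenceError, HHNetError) as exc:
                    emit_failure(exposure, rnd, model_name, "OR", exc)
        try:
            pooled = fit_multilevel_logistic(data, exposure, tuple(covariates), n_quad=n_quad)
            emit_or(exposure, "all", "pooled", pooled)
            for me in average_marginal_effect(pooled, exposure, re_treatment=re_treatment):
                from scipy.stats import norm

                p = 2 * norm.sf(abs(me.me_pp / me.se_pp)) if me.se_pp > 0 else np.nan
                emit(exposure, me.level, "all", "pooled", "ME_pp", me.me_pp,
                     me.ci95_pp[0], me.ci95_pp[1], p, pooled.n_used, True)
        except (ConvergenceError, HHNetError) as exc:
            emit_failure(exposure, "all", "pooled", "OR", exc)
    return pd.DataFrame(rows)
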