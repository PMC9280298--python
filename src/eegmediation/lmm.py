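"""Random-intercept linear mixed models for repeated-measures trial data.

The model is ``y = X beta + u[subject] + e`` with independent subject
intercepts u ~ N(0, sigma_u^2) and residuals e ~ N(0, sigma_e^2).
Estimation profiles the variance ratio gamma = sigma_u^2 / sigma_e^2:
for a fixed gamma the GLS solution and the profiled (restricted)
log-likelihood have closed forms via the Woodbury identity on each
subject's block, so the fit reduces to a one-dimensional optimization
that is robust at the very small sample sizes typical of early-phase
trials (here ~25 subjects x 2 visits).

P-values use the Wald normal approximation by default, with an optional
Satterthwaite-style degrees-of-freedom correction (numeric, from the
curvature of the REML surface in the variance components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of a random-intercept model.

    ``fixed_effects`` are column names of the data frame; an intercept
    is always included first.  ``method`` is REML (reported fits) or ML
    (used inside power-simulation refits).
    """

    response: str
    fixed_effects: tuple[str, ...]
    groups: str = "subject_id"
    method: str = "REML"
    p_value_mode: str = "wald-z"       # or "satterthwaite"

    def __post_init__(self) -> None:
        if self.method not in ("REML", "ML"):
            raise ValueError(f"method must be REML or ML, got {self.method}")
        if self.p_value_mode not in ("wald-z", "satterthwaite"):
            raise ValueError(f"unknown p_value_mode {self.p_value_mode}")


@dataclass
class LMMFit:
    """Fitted random-intercept model."""

    beta: pd.Series
    vcov_beta: pd.DataFrame
    sigma2_subject: float
    sigma2_resid: float
    se: pd.Series
    p_values: pd.Series
    df: pd.Series
    method: str
    converged: bool
    n_obs: int
    n_groups: int
    reml_criterion: float
    spec: ModelSpec
    # design retained for simulation-based power analysis
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    group_codes: np.ndarray = field(repr=False, default=None)

    @property
    def term_names(self) -> list[str]:
        return list(self.beta.index)


class _ProfiledREML:
    """Closed-form profiled criterion for the variance ratio gamma.

    Precomputes X'X, X'y, y'y and per-group sums so each criterion
    evaluation is O(g p^2).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, codes: np.ndarray,
                 reml: bool):
        self.X, self.y, self.reml = X, y, reml
        self.n, self.p = X.shape
        g = codes.max() + 1
        self.sizes = np.bincount(codes, minlength=g).astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-group sums of rows of X and of y
        self.Gx = np.zeros((g, self.p))
        np.add.at(self.Gx, codes, X)
        self.Gy = np.bincount(codes, weights=y, minlength=g)

    def components(self, gamma: float):
        w = gamma / (1.0 + gamma * self.sizes)
        A = self.XtX - self.Gx.T @ (w[:, None] * self.Gx)
        b = self.Xty - self.Gx.T @ (w * self.Gy)
        yVy = self.yty - float(w @ self.Gy ** 2)
        beta = np.linalg.solve(A, b)
        rss = yVy - float(b @ beta)
        logdetV = float(np.sum(np.log1p(gamma * self.sizes)))
        return A, beta, max(rss, 1e-300), logdetV

    def criterion(self, gamma: float) -> float:
        """-2 x profiled (restricted) log-likelihood, up to a constant."""
        A, _, rss, logdetV = self.components(gamma)
        if self.reml:
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            return logdetV + logdetA + (self.n - self.p) * np.log(rss)
        return logdetV + self.n * np.log(rss)


def _build_design(spec: ModelSpec, data: pd.DataFrame):
    cols = ["(Intercept)"] + list(spec.fixed_effects)
    needed = [spec.response, *spec.fixed_effects, spec.groups]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing columns {missing}")
    y = data[spec.response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(data))] +
        [data[c].to_numpy(dtype=float) for c in spec.fixed_effects])
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("model columns contain non-finite values")
    codes, levels = pd.factorize(data[spec.groups])
    if len(levels) < 2:
        raise ValueError("grouping factor must have at least 2 levels")
    # singular-design check with named columns
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [cols[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"singular design; collinear column(s): {bad}")
    return y, X, codes, cols, len(levels)


def fit_random_intercept(spec: ModelSpec, data: pd.DataFrame) -> LMMFit:
    """Fit the random-intercept model by profiled (RE)ML."""
    y, X, codes, cols, n_groups = _build_design(spec, data)
    n, p = X.shape
    prof = _ProfiledREML(X, y, codes, reml=(spec.method == "REML"))

    res = optimize.minimize_scalar(
        lambda psi: prof.criterion(np.exp(psi)),
        bounds=(-20.0, 15.0), method="bounded",
        options={"xatol": 1e-10})
    converged = bool(res.success)
    if not converged:
        warnings.warn("variance-ratio optimization did not converge; "
                      "returning the best point found", stacklevel=2)
    gamma = float(np.exp(res.x))
    if prof.criterion(0.0) <= res.fun:        # boundary: no subject variance
        gamma = 0.0

    A, beta, rss, _ = prof.components(gamma)
    denom = (n - p) if spec.method == "REML" else n
    sigma2_resid = rss / denom
    sigma2_subject = gamma * sigma2_resid
    vcov = sigma2_resid * np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)

    if spec.p_value_mode == "satterthwaite":
        dof = _satterthwaite_df(X, codes, sigma2_subject, sigma2_resid, prof)
        pvals = 2.0 * stats.t.sf(np.abs(z), dof)
    else:
        dof = np.full(p, np.inf)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.where(se > 0, pvals, 1.0)

    return LMMFit(
        beta=pd.Series(beta, index=cols, name="estimate"),
        vcov_beta=pd.DataFrame(vcov, index=cols, columns=cols),
        sigma2_subject=float(sigma2_subject),
        sigma2_resid=float(sigma2_resid),
        se=pd.Series(se, index=cols, name="se"),
        p_values=pd.Series(pvals, index=cols, name="p"),
        df=pd.Series(dof, index=cols, name="df"),
        method=spec.method, converged=converged,
        n_obs=n, n_groups=n_groups,
        reml_criterion=float(prof.criterion(gamma)),
        spec=spec, X=X, y=y, group_codes=codes)


def _reml_loglik_theta(X, y, codes, theta) -> float:
    """REML log-likelihood (up to constant) in theta = (s2_u, s2_e)."""
    s2u, s2e = theta
    if s2e <= 0 or s2u < 0:
        return -np.inf
    n, p = X.shape
    gamma = s2u / s2e
    prof = _ProfiledREML(X, y, codes, reml=True)
    A, beta, rss, logdetV = prof.components(gamma)
    sign, logdetA = np.linalg.slogdet(A / s2e)
    return -0.5 * (logdetV + n * np.log(s2e) + logdetA + rss / s2e)


def _satterthwaite_df(X, codes, s2u, s2e, prof) -> np.ndarray:
    """Numeric Satterthwaite-style degrees of freedom per coefficient.

    df_j = 2 g_j^2 / (grad_j' A grad_j) with g_j = Var(beta_j)(theta) and
    A the inverse curvature of the REML surface at theta-hat; gradients
    and the Hessian use central differences.
    """
    p = X.shape[1]
    y = prof.y

    def varbeta(theta):
        gamma = theta[0] / theta[1] if theta[1] > 0 else 0.0
        A, _, _, _ = prof.components(max(gamma, 0.0))
        return theta[1] * np.diag(np.linalg.inv(A))

    theta = np.array([max(s2u, 1e-10), max(s2e, 1e-10)])
    h = np.maximum(1e-4 * theta, 1e-8)
    grads = np.zeros((p, 2))
    for k in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h[k]
        tm[k] = max(tm[k] - h[k], 1e-12)
        grads[:, k] = (varbeta(tp) - varbeta(tm)) / (tp[k] - tm[k])
    # numeric Hessian of -loglik
    H = np.zeros((2, 2))
    f0 = _reml_loglik_theta(X, y, codes, theta)
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            fpp = _reml_loglik_theta(X, y, codes, theta + ei + ej)
            fpm = _reml_loglik_theta(X, y, codes, theta + ei - ej)
            fmp = _reml_loglik_theta(X, y, codes, theta - ei + ej)
            fmm = _reml_loglik_theta(X, y, codes, theta - ei - ej)
            H[i, j] = H[j, i] = -(fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        Acov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(p, np.inf)
    g = varbeta(theta)
    quad = np.einsum("pi,ij,pj->p", grads, Acov, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * g ** 2 / quad
    df = np.where((quad > 0) & np.isfinite(df), df, np.inf)
    return np.maximum(df, 1.0)


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def wald_table(fit: LMMFit) -> pd.DataFrame:
    """Coefficient table mirroring the published fixed-effect tables."""
    stat = np.divide(fit.beta.to_numpy(), fit.se.to_numpy(),
                     out=np.zeros(len(fit.beta)),
                     where=fit.se.to_numpy() > 0)
    return pd.DataFrame({
        "Variables": fit.term_names,
        "Estimate": fit.beta.to_numpy(),
        "SE": fit.se.to_numpy(),
        "statistic": stat,
        "P-value": fit.p_values.to_numpy(),
        "code": [significance_code(p) for p in fit.p_values],
    })
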