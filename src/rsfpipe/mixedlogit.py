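"""Random-intercept logistic regression by adaptive Gauss-Hermite quadrature.

The marginal likelihood integrates each group's Bernoulli likelihood over a
Gaussian random intercept b_i ~ N(0, sigma_b^2):

    L = prod_i  integral  prod_j Bernoulli(y_ij | logistic(x_ij' beta + b))
                phi(b; 0, sigma_b^2) db

The 1-D integral per group is evaluated with Gauss-Hermite quadrature
recentered at the conditional mode of b and rescaled by the conditional
curvature (adaptive quadrature, 15 nodes by default).  sigma_b is optimized
on the log scale; the gradient uses Fisher's identity (posterior expectation
of the complete-data score) on the same nodes.  Standard errors come from
the inverse numerical Hessian of the marginal log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logsumexp

__all__ = ["MixedLogitResult", "fit_mixed_logit", "marginal_loglik"]

_LOG_SIGMA_FLOOR = np.log(1e-6)
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class MixedLogitResult:
    beta: np.ndarray  # fixed effects, first entry = intercept if X has one
    sigma_b: float
    loglik: float
    aic: float
    se: np.ndarray  # standard errors of the fixed effects
    se_log_sigma: float
    cov: np.ndarray  # covariance of (beta, log sigma_b)
    n_obs: int
    n_groups: int
    n_nodes: int
    converged: bool
    boundary: bool  # sigma_b pinned at (numerically) zero
    grad_norm: float
    message: str = ""
    names: list[str] = field(default_factory=list)

    @property
    def k_params(self) -> int:
        """Fixed effects + one variance component, the AIC parameter count."""
        return len(self.beta) + 1


class _Workspace:
    """Precomputed per-dataset arrays shared across likelihood evaluations."""

    def __init__(self, X, y, groups, n_nodes):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        uniq, g = np.unique(groups, return_inverse=True)
        self.g = g
        self.G = len(uniq)
        self.group_labels = uniq
        z, w = np.polynomial.hermite.hermgauss(n_nodes)
        self.z = z
        self.logw_adj = np.log(w) + z * z  # log w_k + z_k^2
        self.b_hat = np.zeros(self.G)  # warm start across evaluations

    def modes(self, xb, sigma2):
        """Conditional mode and curvature of b per group (Newton, concave)."""
        b = self.b_hat.copy()
        g, y = self.g, self.y
        for _ in range(60):
            eta = xb + b[g]
            mu = expit(eta)
            score = np.bincount(g, weights=y - mu, minlength=self.G) - b / sigma2
            W = np.bincount(g, weights=mu * (1.0 - mu), minlength=self.G)
            hess = W + 1.0 / sigma2
            step = score / hess
            np.clip(step, -5.0, 5.0, out=step)
            b += step
            if np.max(np.abs(step)) < 1e-11:
                break
        self.b_hat = b
        eta = xb + b[g]
        mu = expit(eta)
        W = np.bincount(g, weights=mu * (1.0 - mu), minlength=self.G)
        tau = 1.0 / np.sqrt(W + 1.0 / sigma2)
        return b, tau


def _group_loglik_terms(ws: _Workspace, xb, b_nodes, sigma, sigma2):
    """h_i(b_k) for every group i and node k; shape (G, K)."""
    G, K = ws.G, len(ws.z)
    h = np.empty((G, K))
    y, g = ws.y, ws.g
    for k in range(K):
        eta = xb + b_nodes[:, k][g]
        ll_rows = y * eta - np.logaddexp(0.0, eta)
        h[:, k] = np.bincount(g, weights=ll_rows, minlength=G)
    h += -(b_nodes**2) / (2.0 * sigma2) - np.log(sigma) - _HALF_LOG_2PI
    return h


def _loglik_and_grad(params, ws: _Workspace, want_grad=True):
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    sigma2 = sigma * sigma
    xb = ws.X @ beta
    b_hat, tau = ws.modes(xb, sigma2)
    b_nodes = b_hat[:, None] + np.sqrt(2.0) * tau[:, None] * ws.z[None, :]
    h = _group_loglik_terms(ws, xb, b_nodes, sigma, sigma2)
    log_terms = ws.logw_adj[None, :] + h
    li = np.log(np.sqrt(2.0) * tau) + logsumexp(log_terms, axis=1)
    ll = float(li.sum())
    if not want_grad:
        return ll, None
    # Fisher identity: d l_i / d theta = E_{b|y}[ d h / d theta ]
    post = np.exp(log_terms - logsumexp(log_terms, axis=1, keepdims=True))
    resid_w = np.zeros(len(ws.y))
    g = ws.g
    for k in range(len(ws.z)):
        eta = xb + b_nodes[:, k][g]
        resid_w += post[:, k][g] * (ws.y - expit(eta))
    grad_beta = ws.X.T @ resid_w
    grad_ls = float(np.sum(post * (b_nodes**2 / sigma2 - 1.0)))
    return ll, np.append(grad_beta, grad_ls)


def marginal_loglik(beta, sigma_b, X, y, groups, n_nodes: int = 15) -> float:
    """Marginal log-likelihood at (beta, sigma_b) by adaptive quadrature."""
    ws = _Workspace(X, y, groups, n_nodes)
    sigma_b = max(float(sigma_b), np.exp(_LOG_SIGMA_FLOOR))
    ll, _ = _loglik_and_grad(np.append(beta, np.log(sigma_b)), ws, want_grad=False)
    return ll


def _numerical_hessian(fun, params, rel_step=1e-5):
    p = len(params)
    H = np.empty((p, p))
    steps = rel_step * np.maximum(1.0, np.abs(params))
    for j in range(p):
        e = np.zeros(p)
        e[j] = steps[j]
        _, gp = fun(params + e)
        _, gm = fun(params - e)
        H[:, j] = (gp - gm) / (2.0 * steps[j])
    return 0.5 * (H + H.T)


def _glm_start(X, y):
    """Plain logistic Newton fit for starting values (internal, not the oracle)."""
    beta = np.zeros(X.shape[1])
    for _ in range(30):
        eta = X @ beta
        mu = expit(eta)
        W = np.maximum(mu * (1.0 - mu), 1e-10)
        try:
            step = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -3.0, 3.0)
        beta += step
        if np.max(np.abs(step)) < 1e-9:
            break
    return beta


def fit_mixed_logit(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    n_nodes: int = 15,
    grad_tol: float = 1e-6,
    fix_sigma_b: float | None = None,
) -> MixedLogitResult:
    """Fit the random-intercept logistic model by maximum marginal likelihood.

    Parameters
    ----------
    X : (n, p) design matrix including any intercept column.
    y : (n,) binary response in {0, 1}.
    groups : (n,) group (individual) labels.
    n_nodes : Gauss-Hermite nodes for the adaptive quadrature.
    grad_tol : infinity-norm gradient threshold declaring convergence.
    fix_sigma_b : if given, the random-intercept SD is held at this value
        (profile fit); 0 reduces the model to plain logistic regression
        evaluated through the same quadrature machinery.

    Degenerate responses (all 0 or all 1) and apparent separation yield a
    flagged result with ``converged=False`` rather than an exception; a
    rank-deficient design raises ``ValueError``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, p) with n matching y")
    names = names or [f"x{j}" for j in range(X.shape[1])]
    p = X.shape[1]
    nan_res = MixedLogitResult(
        beta=np.full(p, np.nan), sigma_b=np.nan, loglik=np.nan, aic=np.nan,
        se=np.full(p, np.nan), se_log_sigma=np.nan, cov=np.full((p + 1, p + 1), np.nan),
        n_obs=len(y), n_groups=len(np.unique(groups)), n_nodes=n_nodes,
        converged=False, boundary=False, grad_norm=np.inf, names=names,
    )
    if len(np.unique(y)) < 2:
        nan_res.message = "degenerate response: y is constant"
        return nan_res
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    ws = _Workspace(X, y, groups, n_nodes)
    beta0 = _glm_start(X, y)
    fixed = fix_sigma_b is not None
    if fixed:
        ls_fix = max(np.log(max(fix_sigma_b, 0.0)) if fix_sigma_b > 0 else -np.inf,
                     _LOG_SIGMA_FLOOR)
        x0 = np.append(beta0, ls_fix)
        bounds = [(None, None)] * p + [(ls_fix, ls_fix)]
    else:
        x0 = np.append(beta0, np.log(0.5))
        bounds = [(None, None)] * p + [(_LOG_SIGMA_FLOOR, np.log(50.0))]

    def negloglik(params):
        ll, grad = _loglik_and_grad(params, ws)
        return -ll, -grad

    opt = optimize.minimize(
        negloglik, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
    )
    params = opt.x
    # Newton polish on the analytic gradient to push the score to ~0.
    for _ in range(25):
        ll, grad = _loglik_and_grad(params, ws)
        at_floor = fixed or params[-1] <= _LOG_SIGMA_FLOOR + 1e-9
        g_chk = grad[:-1] if at_floor else grad
        if np.max(np.abs(g_chk)) < grad_tol / 10:
            break
        H = _numerical_hessian(lambda q: _loglik_and_grad(q, ws), params)
        try:
            if at_floor:
                step = np.append(np.linalg.solve(H[:p, :p], grad[:p]), 0.0)
            else:
                step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        step = np.clip(-step, -1.0, 1.0)
        cand = params + step
        cand[-1] = max(cand[-1], _LOG_SIGMA_FLOOR)
        ll_new, _ = _loglik_and_grad(cand, ws, want_grad=False)
        if not np.isfinite(ll_new) or ll_new < ll - 1e-8:
            break
        params = cand

    ll, grad = _loglik_and_grad(params, ws)
    beta = params[:-1]
    sigma = float(np.exp(params[-1]))
    boundary = bool(fixed or params[-1] <= _LOG_SIGMA_FLOOR + 1e-6)
    g_chk = grad[:-1] if boundary else grad
    grad_norm = float(np.max(np.abs(g_chk)))
    H = _numerical_hessian(lambda q: _loglik_and_grad(q, ws), params)
    cov = np.full((p + 1, p + 1), np.nan)
    se = np.full(p, np.nan)
    se_ls = np.nan
    try:
        if boundary:
            # log sigma direction is flat at the floor; invert the beta block
            cov_bb = np.linalg.inv(-H[:p, :p])
            if np.all(np.diag(cov_bb) > 0):
                cov[:p, :p] = cov_bb
                se = np.sqrt(np.diag(cov_bb))
        else:
            cov_full = np.linalg.inv(-H)
            if np.all(np.diag(cov_full)[:p] > 0):
                cov = cov_full
                se = np.sqrt(np.diag(cov_full)[:p])
                se_ls = float(np.sqrt(cov_full[p, p])) if cov_full[p, p] > 0 else np.nan
    except np.linalg.LinAlgError:
        pass
    converged = bool(grad_norm < grad_tol and np.all(np.isfinite(se)))
    k = p + 1  # fixed effects + one variance component
    return MixedLogitResult(
        beta=beta,
        sigma_b=(float(fix_sigma_b) if fixed else 0.0 if boundary else sigma),
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        se=se,
        se_log_sigma=se_ls,
        cov=cov,
        n_obs=len(y),
        n_groups=ws.G,
        n_nodes=n_nodes,
        converged=converged,
        boundary=boundary,
        grad_norm=grad_norm,
        message=opt.message if isinstance(opt.message, str) else "",
        names=names,
    )
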