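"""Random-intercept linear mixed model with Satterthwaite degrees of freedom.

The single-trial ERP analyses need y = X beta + Z b + e with one random
intercept per participant, REML estimation, and per-coefficient t statistics
on Satterthwaite-approximated df. For this structure the marginal covariance
is block diagonal, V_j = sigma^2 (I + lambda 1 1') with lambda = tau^2 /
sigma^2, so the REML criterion reduces to per-group sufficient statistics
(O(groups x p^2) per evaluation) and the profile over lambda is a fast 1-D
optimisation.

Satterthwaite df for coefficient c follow the standard recipe
df = 2 f^2 / (g' A g), where f(theta) = Var(beta_c | theta) at the REML
estimate theta = (tau^2, sigma^2), g is the gradient of f, and A is the
asymptotic covariance of theta (inverse observed REML information); both
derivatives are obtained by central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import t as t_dist


@dataclass
class RandomInterceptFit:
    terms: list[str]
    params: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    dfs: np.ndarray              # Satterthwaite-approximated
    pvalues: np.ndarray
    sigma2: float                # residual variance
    tau2: float                  # random-intercept variance
    deviance: float              # -2 REML log-likelihood (up to a constant)
    n_obs: int
    n_groups: int
    singular: bool               # random-intercept variance estimated at zero

    def summary_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "term": self.terms, "estimate": self.params, "se": self.se,
            "t": self.tvalues, "df": self.dfs, "p": self.pvalues,
        })


class _Suffstats:
    """Per-group sufficient statistics for the random-intercept REML criterion."""

    def __init__(self, X, y, groups):
        self.n, self.p = X.shape
        codes, _ = _factorise(groups)
        self.g = codes.max() + 1
        self.A = np.zeros((self.g, self.p, self.p))
        self.s = np.zeros((self.g, self.p))
        self.u = np.zeros((self.g, self.p))
        self.ty = np.zeros(self.g)
        self.q = np.zeros(self.g)
        self.sizes = np.bincount(codes, minlength=self.g).astype(float)
        for j in range(self.g):
            m = codes == j
            Xj, yj = X[m], y[m]
            self.A[j] = Xj.T @ Xj
            self.s[j] = Xj.sum(axis=0)
            self.u[j] = Xj.T @ yj
            self.ty[j] = yj.sum()
            self.q[j] = yj @ yj

    def gls_pieces(self, lam):
        c = lam / (1.0 + self.sizes * lam)
        M = self.A.sum(axis=0) - np.einsum("j,ji,jk->ik", c, self.s, self.s)
        v = self.u.sum(axis=0) - (c * self.ty) @ self.s
        q = self.q.sum() - np.sum(c * self.ty ** 2)
        return M, v, q

    def profiled_deviance(self, lam):
        """-2 REML log-likelihood with beta and sigma^2 profiled out."""
        M, v, q = self.gls_pieces(lam)
        beta = np.linalg.solve(M, v)
        rss = q - beta @ v
        dof = self.n - self.p
        sigma2 = rss / dof
        sign, logdet_m = np.linalg.slogdet(M)
        if sign <= 0 or sigma2 <= 0:
            return np.inf
        return (dof * np.log(sigma2) + np.sum(np.log1p(self.sizes * lam))
                + logdet_m + dof)

    def deviance(self, tau2, sigma2):
        """-2 REML log-likelihood at explicit variance components."""
        lam = tau2 / sigma2
        M, v, q = self.gls_pieces(lam)
        beta = np.linalg.solve(M, v)
        rss = q - beta @ v
        sign, logdet_m = np.linalg.slogdet(M)
        dof = self.n - self.p
        return (dof * np.log(sigma2) + np.sum(np.log1p(self.sizes * lam))
                + logdet_m + rss / sigma2)

    def coef_variances(self, tau2, sigma2):
        """Diagonal of Var(beta_hat) = sigma^2 M(lambda)^{-1}."""
        M, _, _ = self.gls_pieces(tau2 / sigma2)
        return sigma2 * np.diag(np.linalg.inv(M))


def _factorise(groups):
    values = np.asarray(groups)
    uniq, codes = np.unique(values, return_inverse=True)
    return codes, uniq


def _satterthwaite_dfs(ss: _Suffstats, tau2: float, sigma2: float) -> np.ndarray:
    theta = np.array([tau2, sigma2])
    h = 1e-5 * np.maximum(theta, 1e-3 * sigma2)
    # keep tau2 - 2h >= 0 so central differences never cross the boundary
    h[0] = min(h[0], tau2 / 2) if tau2 > 0 else h[0]

    def dev(th):
        return ss.deviance(max(th[0], 0.0), th[1])

    def fvals(th):
        return ss.coef_variances(max(th[0], 0.0), th[1])

    grads = np.zeros((ss.p, 2))
    for i in range(2):
        hi, lo = theta.copy(), theta.copy()
        hi[i] += h[i]
        lo[i] -= h[i]
        grads[:, i] = (fvals(hi) - fvals(lo)) / (2 * h[i])

    # observed REML information: half the Hessian of the deviance (-2 log L),
    # so Var(theta_hat) = 2 * Hessian^{-1}
    hess = np.zeros((2, 2))
    for i in range(2):
        for k in range(i, 2):
            pts = []
            for si, sk in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                th = theta.copy()
                th[i] += si * h[i]
                th[k] += sk * h[k]
                pts.append(dev(th))
            hess[i, k] = hess[k, i] = (pts[0] - pts[1] - pts[2] + pts[3]) \
                / (4 * h[i] * h[k])
    try:
        cov_theta = 2.0 * np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_theta = 2.0 * np.linalg.pinv(hess)

    f = ss.coef_variances(tau2, sigma2)
    denom = np.einsum("ci,ik,ck->c", grads, cov_theta, grads)
    dfs = np.full(ss.p, float(ss.n - ss.p))
    ok = denom > 0
    dfs[ok] = 2.0 * f[ok] ** 2 / denom[ok]
    return np.clip(dfs, 1.0, float(ss.n - ss.p))


def fit_random_intercept(X, y, groups, terms: list[str] | None = None) -> RandomInterceptFit:
    """REML fit of y ~ X with a random intercept per level of ``groups``.

    ``X`` must include an intercept column if one is wanted. With a single
    group the model degenerates to ordinary least squares (tau^2 = 0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    terms = list(terms) if terms is not None else [f"x{i}" for i in range(X.shape[1])]
    ss = _Suffstats(X, y, groups)

    res = optimize.minimize_scalar(lambda z: ss.profiled_deviance(np.exp(z)),
                                   bounds=(-20.0, 12.0), method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    # the boundary lambda -> 0 (no group variance) can beat any interior point
    if ss.profiled_deviance(0.0) <= res.fun:
        lam = 0.0
    singular = lam < 1e-8

    M, v, q = ss.gls_pieces(lam)
    beta = np.linalg.solve(M, v)
    rss = q - beta @ v
    sigma2 = rss / (ss.n - ss.p)
    tau2 = lam * sigma2
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(M)))
    tvals = beta / se
    if singular:
        dfs = np.full(ss.p, float(ss.n - ss.p))
    else:
        dfs = _satterthwaite_dfs(ss, tau2, sigma2)
    pvals = 2.0 * t_dist.sf(np.abs(tvals), dfs)
    return RandomInterceptFit(
        terms=terms, params=beta, se=se, tvalues=tvals, dfs=dfs, pvalues=pvals,
        sigma2=float(sigma2), tau2=float(tau2),
        deviance=float(ss.deviance(tau2, sigma2)),
        n_obs=ss.n, n_groups=ss.g, singular=bool(singular),
    )
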