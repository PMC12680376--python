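"""Random-intercept linear mixed model with Satterthwaite inference.

The model is ``y = X beta + b_subject + e`` with ``b ~ N(0, sigma_b^2)`` and
``e ~ N(0, sigma_e^2)``.  The variance ratio is estimated by maximum
likelihood (profiled closed form for the residual variance); fixed-effect
covariances, Wald F tests, and Satterthwaite denominator degrees of freedom
follow from the fitted variance components.  The single-grouping structure
admits Woodbury-style closed forms, so no general mixed-model solver is
needed; correctness is cross-checked against statsmodels' MixedLM in the
test suite.

For Wald inference the residual variance uses the degrees-of-freedom
corrected scale ``r' W^-1 r / (n - p)`` so that at a zero random-intercept
variance the F statistics coincide exactly with ordinary fixed-effects
ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

from reinstate.errors import RankDeficientDesignError

_EIG_TOL = 1e-10


def _check_rank(X, column_names):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        aliased = [column_names[j] for j in piv[rank:]]
        raise RankDeficientDesignError(aliased)


@dataclass
class RandomInterceptModel:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    column_names: list
    n_obs: int
    n_groups: int
    loglik: float
    df_fallback: float
    _profile: object = field(default=None, repr=False)
    _theta_cov: np.ndarray = field(default=None, repr=False)

    # -- inference ---------------------------------------------------------

    def contrast(self, c):
        """Estimate, t, Satterthwaite df, and two-sided p for c' beta."""
        c = np.asarray(c, dtype=float)
        b = float(c @ self.beta)
        var = float(c @ self.cov_beta @ c)
        se = np.sqrt(var)
        t = b / se if se > 0 else np.inf * np.sign(b)
        df = self._satterthwaite_df(c)
        p = float(2 * sps.t.sf(abs(t), df))
        return b, t, df, p

    def wald_f(self, L):
        """Omnibus F for L beta = 0 with Satterthwaite denominator df."""
        L = np.atleast_2d(np.asarray(L, dtype=float))
        q = L.shape[0]
        Lb = L @ self.beta
        M = L @ self.cov_beta @ L.T
        F = float(Lb @ np.linalg.solve(M, Lb) / q)
        # per-eigencontrast Satterthwaite dfs combined as in lmerTest
        d, P = np.linalg.eigh(M)
        nus = []
        for i in range(q):
            if d[i] <= _EIG_TOL * d.max():
                continue
            nus.append(self._satterthwaite_df(P[:, i] @ L))
        nus = [nu for nu in nus if nu > 2]
        if nus:
            E = sum(nu / (nu - 2) for nu in nus)
            df2 = 2 * E / (E - q) if E > q else self.df_fallback
        else:
            df2 = self.df_fallback
        df2 = float(np.clip(df2, 1.0, 1e7))
        p = float(sps.f.sf(F, q, df2))
        return F, float(q), df2, p

    def _satterthwaite_df(self, c):
        if self._profile is None or self._theta_cov is None:
            return self.df_fallback
        f0, grad = self._profile.contrast_var_grad(np.asarray(c, dtype=float))
        denom = float(grad @ self._theta_cov @ grad)
        if not np.isfinite(denom) or denom <= 0:
            return self.df_fallback
        nu = 2.0 * f0**2 / denom
        if not np.isfinite(nu) or nu < 1:
            return self.df_fallback
        return float(min(nu, 1e7))


class _Profile:
    """Closed-form GLS pieces for the single random-intercept structure."""

    def __init__(self, y, X, codes, n_groups):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.codes = codes
        self.n_groups = n_groups
        self.counts = np.bincount(codes, minlength=n_groups).astype(float)
        # per-group sums of X rows and y
        self.Sx = np.zeros((n_groups, self.p))
        np.add.at(self.Sx, codes, X)
        self.Sy = np.bincount(codes, weights=y, minlength=n_groups)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def gls(self, lam):
        """Return (A, beta, rwr, logdetW) for W = I + lam * ZZ'."""
        c = lam / (1.0 + self.counts * lam)
        A = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        b = self.Xty - self.Sx.T @ (c * self.Sy)
        beta = np.linalg.solve(A, b)
        rwr = self.yty - float(c @ self.Sy**2) - float(b @ beta)
        logdetW = float(np.sum(np.log1p(self.counts * lam)))
        return A, beta, max(rwr, 1e-300), logdetW

    def neg_loglik_lambda(self, lam):
        """Profile (over beta and sigma_e) ML deviance / 2 at given lambda."""
        _, _, rwr, logdetW = self.gls(lam)
        s2 = rwr / self.n
        return 0.5 * (self.n * (np.log(2 * np.pi * s2) + 1.0) + logdetW)

    def neg_loglik_theta(self, theta):
        """ML negative log-likelihood at (sigma_b^2, sigma_e^2), beta profiled."""
        s2b, s2e = theta
        if s2e <= 0 or s2b < 0:
            return np.inf
        lam = s2b / s2e
        _, _, rwr, logdetW = self.gls(lam)
        return 0.5 * (
            self.n * np.log(2 * np.pi * s2e) + logdetW + rwr / s2e
        )

    def cov_beta(self, theta, df_correct=True):
        s2b, s2e = theta
        lam = s2b / s2e
        A, _, _, _ = self.gls(lam)
        scale = s2e * self.n / (self.n - self.p) if df_correct else s2e
        return scale * np.linalg.inv(A)

    def contrast_var_grad(self, c, rel_step=1e-4):
        """Value and finite-difference gradient of c' Cov(beta) c in theta."""
        theta = self.theta
        f0 = float(c @ self.cov_beta(theta) @ c)
        grad = np.zeros(2)
        for j in range(2):
            h = max(rel_step * abs(theta[j]), 1e-8)
            tp = theta.copy()
            tm = theta.copy()
            tp[j] += h
            tm[j] = max(tm[j] - h, 0.0 if j == 0 else 1e-12)
            fp = float(c @ self.cov_beta(tp) @ c)
            fm = float(c @ self.cov_beta(tm) @ c)
            grad[j] = (fp - fm) / (tp[j] - tm[j])
        return f0, grad

    def theta_cov(self):
        """Inverse numeric Hessian of the negative log-likelihood at theta."""
        theta = self.theta
        if theta[0] <= 1e-10:  # boundary: curvature in sigma_b^2 unreliable
            return None
        H = np.zeros((2, 2))
        hs = [max(1e-4 * abs(theta[j]), 1e-8) for j in range(2)]
        f0 = self.neg_loglik_theta(theta)
        for j in range(2):
            for k in range(j, 2):
                tpp = theta.copy(); tpp[j] += hs[j]; tpp[k] += hs[k]
                tpm = theta.copy(); tpm[j] += hs[j]; tpm[k] -= hs[k]
                tmp = theta.copy(); tmp[j] -= hs[j]; tmp[k] += hs[k]
                tmm = theta.copy(); tmm[j] -= hs[j]; tmm[k] -= hs[k]
                H[j, k] = H[k, j] = (
                    self.neg_loglik_theta(tpp)
                    - self.neg_loglik_theta(tpm)
                    - self.neg_loglik_theta(tmp)
                    + self.neg_loglik_theta(tmm)
                ) / (4 * hs[j] * hs[k])
        del f0
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            return None
        return cov


def fit_random_intercept(y, X, groups, column_names=None) -> RandomInterceptModel:
    """ML fit of a random-intercept model; see module docstring."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if column_names is None:
        column_names = [f"x{j}" for j in range(X.shape[1])]
    _check_rank(X, column_names)

    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    prof = _Profile(y, X, codes, len(labels))

    # optimize profile likelihood over log-lambda, comparing with lambda=0
    res = optimize.minimize_scalar(
        lambda t: prof.neg_loglik_lambda(np.exp(t)),
        bounds=(-14.0, 14.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    nll = prof.neg_loglik_lambda(lam)
    nll0 = prof.neg_loglik_lambda(0.0)
    if nll0 <= nll:
        lam, nll = 0.0, nll0

    A, beta, rwr, _ = prof.gls(lam)
    s2e = rwr / prof.n
    s2b = lam * s2e
    prof.theta = np.array([s2b, s2e])
    cov_beta = prof.cov_beta(prof.theta)
    theta_cov = prof.theta_cov()

    return RandomInterceptModel(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_group=float(s2b),
        sigma2_resid=float(s2e),
        column_names=list(column_names),
        n_obs=prof.n,
        n_groups=len(labels),
        loglik=float(-nll),
        df_fallback=float(prof.n - prof.p),
        _profile=prof,
        _theta_cov=theta_cov,
    )
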